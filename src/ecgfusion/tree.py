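"""From-scratch CART over spectral features.

Splits are chosen by maximal Gini impurity decrease (parent impurity minus
child-weighted impurity) over all attributes, with candidate thresholds at
midpoints of consecutive distinct sorted values. Pruning is weakest-link
cost-complexity pruning: the loss C_alpha(T) = C(T) + alpha * |T| with C(T)
the training misclassification count and |T| the leaf count; sweeping alpha
from 0 upward yields a nested chain of subtrees down to the root.

``incremental_train`` implements the fold-rotation scheme: the data is split
into ten equal folds, one held out as the test set; runs t = 1..9 train on
the accumulated folds 1..t (optionally minus "junk" samples the previous
run's pruned tree misclassified), prune, and validate on the eight non-test
folds outside the newest fold; the pruned tree with the highest validation
accuracy across runs is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "CartTree",
    "PrunedTree",
    "IncrementalPlan",
    "IncrementalResult",
    "gini_index",
    "best_split",
    "grow_tree",
    "prune_path",
    "tree_predict",
    "incremental_train",
]


def gini_index(counts: Sequence[float] | np.ndarray) -> float:
    """Gini impurity 1 - sum((n_i / N)^2) of a class-count vector."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n == 0:
        raise ValueError("counts must not be all zero")
    p = c / n
    return float(1.0 - np.sum(p * p))


@dataclass
class Node:
    """One node of a binary CART: internal (attr/threshold) or leaf."""

    id: int
    counts: np.ndarray                    # per-class sample counts at the node
    attr: int | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def distribution(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def misclassified(self) -> int:
        """Training misclassification count if this node were a leaf."""
        return int(self.counts.sum() - self.counts.max())


@dataclass
class CartTree:
    """A grown CART with its class alphabet and (after pruning) alpha chain."""

    root: Node
    classes: tuple[str, ...]
    n_features: int
    alpha_sequence: "list[PrunedTree]" = field(default_factory=list)

    def nodes(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            if not nd.is_leaf:
                stack.extend([nd.left, nd.right])
        return out

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes() if nd.is_leaf)

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(nd: Node) -> dict:
            d = {"id": nd.id, "counts": nd.counts.astype(int).tolist()}
            if not nd.is_leaf:
                d.update(attr=nd.attr, threshold=nd.threshold,
                         left=enc(nd.left), right=enc(nd.right))
            else:
                d["distribution"] = nd.distribution.tolist()
            return d

        doc = {
            "classes": list(self.classes),
            "n_features": self.n_features,
            "root": enc(self.root),
            "alpha_sequence": [
                {"alpha": pt.alpha, "collapsed": sorted(pt.collapsed)}
                for pt in self.alpha_sequence
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CartTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)

        def dec(d: dict) -> Node:
            nd = Node(id=d["id"], counts=np.asarray(d["counts"], dtype=float))
            if "attr" in d:
                nd.attr = d["attr"]
                nd.threshold = d["threshold"]
                nd.left = dec(d["left"])
                nd.right = dec(d["right"])
            return nd

        tree = cls(root=dec(doc["root"]), classes=tuple(doc["classes"]),
                   n_features=doc["n_features"])
        tree.alpha_sequence = [
            PrunedTree(tree=tree, alpha=e["alpha"], collapsed=frozenset(e["collapsed"]))
            for e in doc["alpha_sequence"]
        ]
        return tree


@dataclass
class PrunedTree:
    """A member of the nested pruning chain: the tree with some nodes collapsed."""

    tree: CartTree
    alpha: float
    collapsed: frozenset[int]

    def _descend(self, x: np.ndarray) -> Node:
        nd = self.tree.root
        while not nd.is_leaf and nd.id not in self.collapsed:
            nd = nd.left if x[nd.attr] <= nd.threshold else nd.right
        return nd

    def predict_dist(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.tree.n_features:
            raise ValueError(
                f"expected {self.tree.n_features} features, got {X.shape[1]}")
        return np.stack([self._descend(row).distribution for row in X])

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        dist = self.predict_dist(X)
        return np.asarray(self.tree.classes, dtype=object)[dist.argmax(axis=1)]

    @property
    def n_leaves(self) -> int:
        count = 0
        stack = [self.tree.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf or nd.id in self.collapsed:
                count += 1
            else:
                stack.extend([nd.left, nd.right])
        return count

    @property
    def training_misclassification(self) -> int:
        total = 0
        stack = [self.tree.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf or nd.id in self.collapsed:
                total += nd.misclassified
            else:
                stack.extend([nd.left, nd.right])
        return total


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

def best_split(X: np.ndarray, y_codes: np.ndarray, n_classes: int
               ) -> tuple[int, float, float] | None:
    """Best (attribute, threshold, Gini decrease) or None for a leaf.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values. Ties break to the lowest attribute index, then lowest threshold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_codes = np.asarray(y_codes)
    n, d = X.shape
    if n < 1:
        raise ValueError("need at least one sample")
    counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    parent = gini_index(counts)
    if parent == 0.0 or n < 2:
        return None

    best: tuple[int, float, float] | None = None
    onehot = np.eye(n_classes)[y_codes]
    for a in range(d):
        order = np.argsort(X[:, a], kind="stable")
        vals = X[order, a]
        cum = np.cumsum(onehot[order], axis=0)          # (n, K) left counts
        boundary = np.nonzero(vals[:-1] < vals[1:])[0]  # split after index i
        if boundary.size == 0:
            continue
        nl = (boundary + 1).astype(float)
        nr = n - nl
        left = cum[boundary]
        right = counts - left
        ssl = np.sum(left * left, axis=1)
        ssr = np.sum(right * right, axis=1)
        weighted = 1.0 - (ssl / nl + ssr / nr) / n
        dec = parent - weighted
        j = int(np.argmax(dec))
        if dec[j] > 1e-12 and (best is None or dec[j] > best[2] + 1e-12):
            thr = 0.5 * (vals[boundary[j]] + vals[boundary[j] + 1])
            best = (a, float(thr), float(dec[j]))
    return best


def grow_tree(X: np.ndarray, y: np.ndarray, classes: Sequence[str] | None = None,
              min_samples: int = 1, max_depth: int | None = None) -> CartTree:
    """Grow a CART by recursive binary partitioning until purity or stopping.

    ``min_samples``: a node with at most this many samples becomes a leaf;
    ``max_depth``: maximum number of splits on any root-to-leaf path.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if classes is None:
        classes = tuple(sorted(set(y.tolist())))
    classes = tuple(classes)
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.asarray([code[v] for v in y])
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> Node:
        nd = Node(id=counter[0],
                  counts=np.bincount(y_codes[idx], minlength=len(classes)).astype(float))
        counter[0] += 1
        if (len(idx) <= min_samples
                or (max_depth is not None and depth >= max_depth)):
            return nd
        split = best_split(X[idx], y_codes[idx], len(classes))
        if split is None:
            return nd
        a, thr, _dec = split
        mask = X[idx, a] <= thr
        nd.attr, nd.threshold = a, thr
        nd.left = build(idx[mask], depth + 1)
        nd.right = build(idx[~mask], depth + 1)
        return nd

    root = build(np.arange(X.shape[0]), 0)
    return CartTree(root=root, classes=classes, n_features=X.shape[1])


# ---------------------------------------------------------------------------
# cost-complexity pruning
# ---------------------------------------------------------------------------

def prune_path(tree: CartTree) -> list[PrunedTree]:
    """Weakest-link pruning chain: nested subtrees with increasing alpha.

    Repeatedly collapses the internal node(s) minimizing
    ``g(t) = (C(t as leaf) - C(T_t)) / (|T_t| - 1)`` under the current
    pruned tree; the critical alphas are the successive minima. The chain
    starts at (alpha=0, full tree) and ends at the root-only tree. The chain
    is also stored on ``tree.alpha_sequence``.
    """
    chain: list[PrunedTree] = [PrunedTree(tree=tree, alpha=0.0, collapsed=frozenset())]
    collapsed: set[int] = set()

    def stats(nd: Node) -> tuple[int, int]:
        """(leaf count, subtree misclassification) under current collapse."""
        if nd.is_leaf or nd.id in collapsed:
            return 1, nd.misclassified
        ll, lm = stats(nd.left)
        rl, rm = stats(nd.right)
        return ll + rl, lm + rm

    while True:
        if tree.root.is_leaf or tree.root.id in collapsed:
            break
        # candidate internal nodes still effective in the pruned tree
        cands: list[tuple[float, Node]] = []
        stack = [tree.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf or nd.id in collapsed:
                continue
            leaves, misc = stats(nd)
            g = (nd.misclassified - misc) / (leaves - 1)
            cands.append((g, nd))
            stack.extend([nd.left, nd.right])
        gmin = min(g for g, _ in cands)
        for g, nd in cands:
            if g <= gmin + 1e-12:
                collapsed.add(nd.id)
        alpha = max(float(gmin), chain[-1].alpha)
        member = PrunedTree(tree=tree, alpha=alpha, collapsed=frozenset(collapsed))
        if alpha == chain[-1].alpha:
            # equal-alpha collapses belong to one chain member (keeps alphas
            # strictly increasing and the chain nested)
            chain[-1] = member
        else:
            chain.append(member)
    tree.alpha_sequence = chain
    return chain


def tree_predict(tree: CartTree | PrunedTree, X: np.ndarray) -> np.ndarray:
    """Leaf class distribution(s) reached by root-to-leaf descent."""
    pt = tree if isinstance(tree, PrunedTree) else PrunedTree(
        tree=tree, alpha=0.0, collapsed=frozenset())
    one = np.asarray(X, dtype=float).ndim == 1
    out = pt.predict_dist(X)
    return out[0] if one else out


# ---------------------------------------------------------------------------
# incremental fold-rotation training
# ---------------------------------------------------------------------------

@dataclass
class IncrementalPlan:
    """Fold-rotation schedule for incremental training.

    One of ``n_folds`` equal folds is held out as the test set; the
    remaining folds are consumed one per run in ``train_fold_order``.
    ``junk_rule="misclassified_prev"`` drops pooled training samples the
    previous run's pruned tree misclassified; ``cumulative=False`` trains
    each run on the newest fold only (plain repeated training).
    """

    n_folds: int = 10
    test_fold: int | None = None                 # default: the last fold
    train_fold_order: Sequence[int] | None = None
    junk_rule: str = "misclassified_prev"
    cumulative: bool = True
    seed: int = 0
    min_samples: int = 1
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.junk_rule not in ("off", "misclassified_prev"):
            raise ValueError(f"unknown junk_rule {self.junk_rule!r}")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class IncrementalResult:
    """Outcome of incremental training: the selected tree and the run report."""

    tree: PrunedTree                 # T0: best pruned tree across runs
    report: pd.DataFrame
    folds: list[np.ndarray]
    test_indices: np.ndarray


def incremental_train(X: np.ndarray, y: np.ndarray,
                      plan: IncrementalPlan | None = None) -> IncrementalResult:
    """Fold-rotation incremental CART training with junk-sample elimination.

    The shuffled data is cut into ``n_folds`` near-equal folds; the test
    fold never enters training or validation. Run t grows a tree on the
    accumulated training pool (after junk removal), prunes it, scores every
    chain member on the eight non-test folds outside the newest fold, and
    keeps the best member; the best member across all runs is returned.
    """
    plan = plan or IncrementalPlan()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=object)
    n = X.shape[0]
    if n < plan.n_folds:
        raise ValueError(f"need at least {plan.n_folds} samples, got {n}")

    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(n)
    folds = [f.copy() for f in np.array_split(perm, plan.n_folds)]
    test_fold = plan.test_fold if plan.test_fold is not None else plan.n_folds - 1
    train_folds = [i for i in range(plan.n_folds) if i != test_fold]
    order = list(plan.train_fold_order) if plan.train_fold_order else train_folds
    if sorted(order) != sorted(train_folds):
        raise ValueError("train_fold_order must permute the non-test folds")

    classes = tuple(sorted(set(y.tolist())))
    rows = []
    prev_tree: PrunedTree | None = None
    best: tuple[float, int, PrunedTree] | None = None   # (acc, -run, tree)

    for t, newest in enumerate(order, start=1):
        pool_folds = order[:t] if plan.cumulative else [newest]
        pool = np.concatenate([folds[i] for i in pool_folds])
        junk_removed = 0
        if (plan.junk_rule == "misclassified_prev" and prev_tree is not None):
            pred = prev_tree.predict_label(X[pool])
            keep = pred == y[pool]
            junk_removed = int((~keep).sum())
            if keep.any():                      # never empty the pool outright
                pool = pool[keep]
            else:
                junk_removed = 0
        val_folds = [i for i in train_folds if i != newest]
        val = np.concatenate([folds[i] for i in val_folds])

        grown = grow_tree(X[pool], y[pool], classes=classes,
                          min_samples=plan.min_samples, max_depth=plan.max_depth)
        chain = prune_path(grown)
        accs = [float(np.mean(m.predict_label(X[val]) == y[val])) for m in chain]
        j = int(np.argmax(accs))
        # prefer the simplest chain member among accuracy ties
        for k in range(j + 1, len(chain)):
            if accs[k] >= accs[j]:
                j = k
        run_best = chain[j]
        rows.append({
            "run": t, "newest_fold": newest, "pool_size": len(pool),
            "junk_removed": junk_removed, "n_leaves": run_best.n_leaves,
            "alpha": run_best.alpha, "validation_size": len(val),
            "validation_accuracy": accs[j],
        })
        if best is None or accs[j] > best[0]:
            best = (accs[j], t, run_best)
        prev_tree = run_best

    assert best is not None
    return IncrementalResult(tree=best[2], report=pd.DataFrame(rows),
                             folds=folds, test_indices=folds[test_fold])
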