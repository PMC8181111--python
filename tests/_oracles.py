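"""Independent brute-force oracles for split selection and pruning.

These deliberately re-derive everything by exhaustive enumeration, sharing
no code with the implementation they check.
"""

from itertools import product

import numpy as np

from ecgfusion.tree import CartTree, PrunedTree


def brute_best_split(X, y):
    """Exhaustively score every (attribute, midpoint-threshold) pair.

    Returns (attr, threshold, gini_decrease) with ties broken to the lowest
    attribute index then lowest threshold, or None when nothing improves.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, d = X.shape
    classes = sorted(set(y.tolist()))

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.asarray([np.mean(labels == c) for c in classes])
        return 1.0 - float(np.sum(p * p))

    parent = gini(y)
    best = None
    for a in range(d):
        vals = np.unique(X[:, a])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            mask = X[:, a] <= thr
            w = (mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])) / n
            dec = parent - w
            if dec > 1e-12 and (best is None or dec > best[2] + 1e-12):
                best = (a, thr, dec)
    return best


def enumerate_pruned_subtrees(tree: CartTree):
    """All pruned subtrees, as collapse-sets with no nested collapses."""

    def rec(node):
        if node.is_leaf:
            return [frozenset()]
        below = [l | r for l, r in product(rec(node.left), rec(node.right))]
        return [frozenset({node.id})] + below

    return rec(tree.root)


def brute_min_cost(tree: CartTree, alpha: float):
    """Minimum of C(T) + alpha * |T| over every pruned subtree."""
    best = None
    for collapsed in enumerate_pruned_subtrees(tree):
        pt = PrunedTree(tree=tree, alpha=alpha, collapsed=collapsed)
        cost = pt.training_misclassification + alpha * pt.n_leaves
        if best is None or cost < best:
            best = cost
    return best
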