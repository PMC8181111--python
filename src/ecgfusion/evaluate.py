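"""Metrics, data splitting and the scripted experiment suite.

Metrics follow the one-vs-rest reduction: for each class, sensitivity
Sen = TP/(TP+FN), specificity Spe = TN/(TN+FP), precision Pre = TP/(TP+FP)
and accuracy Acc = (TP+TN)/total, reported in percent per class plus macro
averages. Zero-denominator cells are reported as NaN (not available), never
silently as 0 or 100.

``split_dataset`` produces the shared splits both branches use: the
time-domain branch trains on 80% / validates on 10% / tests on 10%, the
frequency branch uses ten equal folds with the last fold as the test set —
and the time-domain test set and the tree's held-out fold contain the same
beats.

``run_experiment_suite`` reruns the four comparison designs at desk scale
on a synthetic dataset: the band-prefix sweep {5, 25, 45, 65, 85, 105, 125},
segmentation on/off, incremental training on/off, and tree vs GRU vs fused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spectral
from .fusion import FusionConfig, train_fusion
from .gru import TrainConfig, gru_predict, train_gru
from .preprocess import BeatDataset, segment_beats
from .synthetic import SyntheticConfig, make_record, noise_sd_for_snr
from .tree import IncrementalPlan, PrunedTree, grow_tree, incremental_train, prune_path

__all__ = [
    "BAND_GRID",
    "ConfusionCounts",
    "compute_metrics",
    "Splits",
    "split_dataset",
    "SuiteConfig",
    "run_experiment_suite",
]

CLASSES = ("N", "S", "V", "F")
#: Band-prefix sweep grid: 5 bands first, then 20 more at a time up to 125.
BAND_GRID = (5, 25, 45, 65, 85, 105, 125)


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _safe_pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_metrics(y_true, y_pred, classes=CLASSES) -> pd.DataFrame:
    """Per-class and macro-averaged Sen/Spe/Pre/Acc in percent.

    Rows are indexed by class plus a ``macro`` row of nan-aware means.
    """
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    if yt.shape != yp.shape:
        raise ValueError("label sequences must have equal length")
    rows = {}
    for c in classes:
        t, p = yt == c, yp == c
        cc = ConfusionCounts(tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
                             fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)))
        rows[c] = {
            "Sen": _safe_pct(cc.tp, cc.tp + cc.fn),
            "Spe": _safe_pct(cc.tn, cc.tn + cc.fp),
            "Pre": _safe_pct(cc.tp, cc.tp + cc.fp),
            "Acc": _safe_pct(cc.tp + cc.tn, cc.total),
        }
    df = pd.DataFrame(rows).T
    df.loc["macro"] = df.mean(skipna=True)
    return df


def r_peak_detection_stats(truth: np.ndarray, detected: np.ndarray,
                           fs: float, tol_s: float = 0.050) -> dict[str, float]:
    """Sensitivity and positive predictivity of a detector, in percent.

    Detections are matched one-to-one to ground-truth R positions within
    ``tol_s`` seconds (greedy nearest match).
    """
    truth = np.asarray(truth, dtype=int)
    detected = np.asarray(detected, dtype=int)
    tol = int(round(tol_s * fs))
    used: set[int] = set()
    tp = 0
    for d in detected:
        if truth.size == 0:
            break
        order = np.argsort(np.abs(truth - d))
        for j in order[:3]:
            if abs(int(truth[j]) - int(d)) > tol:
                break
            if int(j) not in used:
                used.add(int(j))
                tp += 1
                break
    sen = 100.0 * tp / truth.size if truth.size else float("nan")
    ppv = 100.0 * tp / detected.size if detected.size else float("nan")
    return {"sensitivity": sen, "positive_predictivity": ppv,
            "tp": tp, "n_truth": int(truth.size), "n_detected": int(detected.size)}


def overall_accuracy(y_true, y_pred) -> float:
    """Plain multi-class accuracy in percent."""
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    return float(100.0 * np.mean(yt == yp))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class Splits:
    """Shared dataset splits: 80/10/10 indices plus the ten-fold partition.

    ``folds[-1]`` and ``test`` contain the same beats, so the time-domain
    test set and the tree's held-out fold coincide.
    """

    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    folds: list[np.ndarray] = field(default_factory=list)


def split_dataset(n: int, seed: int = 0, n_folds: int = 10) -> Splits:
    """Shuffle indices with a recorded seed and cut both split schemes."""
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [f.copy() for f in np.array_split(perm, n_folds)]
    test = folds[-1]
    valid = folds[-2]
    train = np.concatenate(folds[:-2])
    return Splits(train=train, valid=valid, test=test, folds=folds)


# ---------------------------------------------------------------------------
# experiment suite
# ---------------------------------------------------------------------------

@dataclass
class SuiteConfig:
    """Desk-scale suite settings: dataset size, noise, and model configs."""

    n_beats: int = 1500
    snr_db: float | None = None          # None: noise-free
    class_mix: tuple = (0.55, 0.15, 0.2, 0.1)
    seed: int = 0
    gru: TrainConfig = field(default_factory=lambda: TrainConfig(
        cell=32, batch_size=64, epochs=12, fc_size=16))
    fusion: FusionConfig = field(default_factory=FusionConfig)
    tree_max_depth: int | None = 12


def make_suite_dataset(config: SuiteConfig) -> BeatDataset:
    """Synthesize, (optionally) noise at a target SNR, and segment beats."""
    base = SyntheticConfig(n_beats=config.n_beats, class_mix=config.class_mix,
                           noise_sd=0.0, baseline_amp=0.0, seed=config.seed)
    record, r_pos, _labels = make_record(base)
    if config.snr_db is not None:
        sd = noise_sd_for_snr(record.lead(0), config.snr_db)
        noisy = SyntheticConfig(n_beats=config.n_beats,
                                class_mix=config.class_mix, noise_sd=sd,
                                baseline_amp=0.05, seed=config.seed)
        record, r_pos, _labels = make_record(noisy)
    return segment_beats(record, r_pos)


def _tree_on_split(features: np.ndarray, y: np.ndarray, splits: Splits,
                   max_depth: int | None) -> tuple[PrunedTree, np.ndarray]:
    """Grow on the 80% split, select a pruned subtree on the 10% validation."""
    grown = grow_tree(features[splits.train], y[splits.train],
                      classes=CLASSES, max_depth=max_depth)
    chain = prune_path(grown)
    accs = [np.mean(m.predict_label(features[splits.valid]) == y[splits.valid])
            for m in chain]
    j = int(np.argmax(accs))
    for k in range(j + 1, len(chain)):
        if accs[k] >= accs[j]:
            j = k
    best = chain[j]
    return best, best.predict_label(features[splits.test])


def run_experiment_suite(config: SuiteConfig | None = None,
                         dataset: BeatDataset | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Run the four comparison designs; returns one table per design.

    Tables: ``band_sweep`` (prefix length vs metrics), ``segmentation``
    (sub-band features on/off), ``incremental`` (fold-rotation training with
    and without junk elimination vs plain training), and ``fusion`` (tree vs
    GRU vs fused on the shared test beats). All metrics are macro averages
    over classes plus overall accuracy, in percent.
    """
    config = config or SuiteConfig()
    ds = dataset if dataset is not None else make_suite_dataset(config)
    X, y = ds.to_matrix()
    n = len(y)
    splits = split_dataset(n, seed=config.seed)

    def macro_row(y_true, y_pred) -> dict[str, float]:
        m = compute_metrics(y_true, y_pred).loc["macro"]
        return {"Sen": m["Sen"], "Spe": m["Spe"], "Pre": m["Pre"],
                "Acc": overall_accuracy(y_true, y_pred)}

    # --- band-prefix sweep (unsegmented features) --------------------------
    full = spectral.beat_features(X, segmented=False)
    band_rows = []
    for k in BAND_GRID:
        feats = spectral.band_prefix(full, k).features
        _tree, pred = _tree_on_split(feats, y, splits, config.tree_max_depth)
        band_rows.append({"bands": k, **macro_row(y[splits.test], pred)})
    band_sweep = pd.DataFrame(band_rows)

    # --- segmentation on/off ----------------------------------------------
    seg = spectral.beat_features(X, segmented=True)
    seg_rows = []
    for name, feats in [("with", seg.features), ("without", full.features)]:
        _tree, pred = _tree_on_split(feats, y, splits, config.tree_max_depth)
        seg_rows.append({"segmentation": name, **macro_row(y[splits.test], pred)})
    segmentation = pd.DataFrame(seg_rows)

    # --- incremental on/off (segmented features) ---------------------------
    inc_rows = []
    for name, junk, cumulative in [("incremental", "misclassified_prev", True),
                                   ("without_incremental", "off", False)]:
        plan = IncrementalPlan(junk_rule=junk, cumulative=cumulative,
                               seed=config.seed, max_depth=config.tree_max_depth)
        res = incremental_train(seg.features, y, plan)
        pred = res.tree.predict_label(seg.features[res.test_indices])
        inc_rows.append({"algorithm": name,
                         **macro_row(y[res.test_indices], pred)})
    incremental = pd.DataFrame(inc_rows)

    # --- tree vs GRU vs fused on the shared test fold ----------------------
    plan = IncrementalPlan(seed=config.seed, max_depth=config.tree_max_depth)
    inc = incremental_train(seg.features, y, plan)
    test = splits.test
    tree_pred = inc.tree.predict_label(seg.features[test])

    gru_params, _trace = train_gru(X[splits.train], y[splits.train],
                                   X[splits.valid], y[splits.valid], config.gru)
    gru_probs, _h = gru_predict(gru_params, X[test])
    gru_pred = np.asarray(CLASSES, dtype=object)[gru_probs.argmax(1)]

    featurizer = lambda beats: spectral.beat_features(beats, segmented=True).features
    model, _ftrace = train_fusion(X[splits.valid], y[splits.valid],
                                  gru_params, inc.tree, featurizer,
                                  config.fusion)
    fused_pred = model.predict_label(X[test])

    fusion_tbl = pd.DataFrame([
        {"algorithm": "Tree", **macro_row(y[test], tree_pred)},
        {"algorithm": "GRU", **macro_row(y[test], gru_pred)},
        {"algorithm": "Fused", **macro_row(y[test], fused_pred)},
    ])
    return {"band_sweep": band_sweep, "segmentation": segmentation,
            "incremental": incremental, "fusion": fusion_tbl}
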