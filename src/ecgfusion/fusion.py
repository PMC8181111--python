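"""Learned per-beat fusion of the GRU and decision-tree branches.

A small 1-D CNN consumes, for each beat, the GRU branch's final hidden
state concatenated with its L2-regularized class logits, and emits two
convex weights (W1 for the GRU branch, W2 for the tree branch) through a
2-way softmax head. The fused prediction is

    softmax(W1 * p_gru + W2 * D_tree)

where ``p_gru`` are the GRU class probabilities and ``D_tree`` the leaf
class distribution from the pruned CART. The CNN is trained by
cross-entropy on the fused outputs over the validation split, with both
branches frozen (two-stage training).

CNN layout: Conv1D (width-3 kernels, SAME padding, ReLU) -> MaxPool1D
(width 2, stride 2, SAME; halves the length) -> global average pooling ->
dropout (identity at inference) -> dense -> 2-way softmax.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gru import GruParams, softmax
from .tree import PrunedTree

__all__ = [
    "FusionConfig",
    "CnnParams",
    "FusionModel",
    "build_fusion_input",
    "cnn_forward",
    "fuse",
    "fit_fusion_cnn",
    "train_fusion",
]


@dataclass
class FusionConfig:
    """Fusion CNN hyper-parameters (filters, kernel width 3, dropout rate)."""

    n_filters: int = 8
    kernel_width: int = 3
    dropout: float = 0.2
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 5e-3
    seed: int = 0


@dataclass
class CnnParams:
    """Weights of the fusion CNN; the dense head always has 2 outputs."""

    kernels: np.ndarray        # (n_filters, kernel_width)
    conv_bias: np.ndarray      # (n_filters,)
    Wd: np.ndarray             # (2, n_filters)
    bd: np.ndarray             # (2,)
    dropout: float = 0.2

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {"kernels": self.kernels, "conv_bias": self.conv_bias,
                  "Wd": self.Wd, "bd": self.bd}
        np.savez(path, **arrays)
        manifest = {"dropout": self.dropout,
                    "shapes": {k: list(a.shape) for k, a in arrays.items()}}
        target = path if path.suffix == ".npz" else Path(f"{path}.npz")
        with zipfile.ZipFile(target, "a") as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CnnParams":
        path = Path(path)
        if path.suffix != ".npz" and not path.exists():
            path = Path(f"{path}.npz")
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files
                      if k in ("kernels", "conv_bias", "Wd", "bd")}
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
        return cls(**arrays, dropout=manifest["dropout"])


def init_cnn(config: FusionConfig, seed: int | None = None) -> CnnParams:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    C, W = config.n_filters, config.kernel_width
    return CnnParams(
        kernels=rng.uniform(-0.3, 0.3, size=(C, W)),
        conv_bias=np.zeros(C),
        Wd=rng.uniform(-0.3, 0.3, size=(2, C)),
        bd=np.zeros(2),
        dropout=config.dropout,
    )


def build_fusion_input(gru_out: tuple[np.ndarray, np.ndarray],
                       gru_params: GruParams) -> np.ndarray:
    """Per-beat CNN input: ``[h_T ; class logits]`` (length cell + K).

    The logit block is recomputed from h_T through the trained (L2
    penalized) fully connected head, so the CNN sees both the hidden
    representation and the regularized output weights acting on it.
    """
    _probs, h = gru_out
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != gru_params.hidden_size:
        raise ValueError("hidden state size does not match GRU parameters")
    o1 = np.tanh(h @ gru_params.W1.T + gru_params.b1)
    logits = o1 @ gru_params.W2.T + gru_params.b2
    u = np.hstack([h, logits])
    return u[0] if np.asarray(gru_out[1]).ndim == 1 else u


# ---------------------------------------------------------------------------
# CNN forward / backward
# ---------------------------------------------------------------------------

def _conv_stack(U: np.ndarray, width: int) -> np.ndarray:
    """(B, L) -> (B, L, width) of zero-padded shifted copies (SAME conv)."""
    B, L = U.shape
    pad = width // 2
    Up = np.pad(U, ((0, 0), (pad, pad)))
    return np.stack([Up[:, j:j + L] for j in range(width)], axis=2)


def _cnn_internals(U: np.ndarray, params: CnnParams,
                   drop_mask: np.ndarray | None = None):
    U = np.atleast_2d(np.asarray(U, dtype=float))
    B, L = U.shape
    stack = _conv_stack(U, params.kernels.shape[1])          # (B, L, W)
    pre = stack @ params.kernels.T + params.conv_bias        # (B, L, C)
    act = np.maximum(pre, 0.0)
    Lp = -(-L // 2)                                          # SAME pool: ceil
    padded = act if 2 * Lp == L else np.pad(
        act, ((0, 0), (0, 2 * Lp - L), (0, 0)), constant_values=-np.inf)
    pairs = padded.reshape(B, Lp, 2, -1)
    arg = pairs.argmax(axis=2)                               # (B, Lp, C)
    pooled = pairs.max(axis=2)
    gap = pooled.mean(axis=1)                                # (B, C)
    dropped = gap if drop_mask is None else gap * drop_mask
    wlogits = dropped @ params.Wd.T + params.bd              # (B, 2)
    weights = softmax(wlogits)
    return {"U": U, "stack": stack, "pre": pre, "arg": arg, "Lp": Lp,
            "gap": gap, "dropped": dropped, "weights": weights}


def cnn_forward(u: np.ndarray, params: CnnParams) -> np.ndarray:
    """Per-beat fusion weights ``(W1, W2)``; dropout is identity at inference.

    Accepts one input vector or a batch of rows; the pair always sums to 1.
    """
    one = np.asarray(u).ndim == 1
    out = _cnn_internals(u, params)["weights"]
    return out[0] if one else out


def fuse(p_gru: np.ndarray, D: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fused class probabilities: softmax(W1 * p_gru + W2 * D)."""
    p = np.atleast_2d(np.asarray(p_gru, dtype=float))
    d = np.atleast_2d(np.asarray(D, dtype=float))
    ww = np.atleast_2d(np.asarray(w, dtype=float))
    if p.shape != d.shape:
        raise ValueError("branch distributions must have the same shape")
    out = softmax(ww[:, 0:1] * p + ww[:, 1:2] * d)
    return out[0] if np.asarray(p_gru).ndim == 1 else out


def fit_fusion_cnn(U: np.ndarray, P: np.ndarray, D: np.ndarray, y_codes,
                   config: FusionConfig | None = None
                   ) -> tuple[CnnParams, pd.DataFrame]:
    """Train the weight CNN by cross-entropy on fused outputs (Adam).

    ``U`` are the fusion inputs, ``P`` the frozen GRU probabilities, ``D``
    the frozen tree distributions and ``y_codes`` integer labels. Returns
    the parameters and a per-epoch trace of loss and mean learned W2.
    """
    config = config or FusionConfig()
    U = np.atleast_2d(np.asarray(U, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    D = np.atleast_2d(np.asarray(D, dtype=float))
    y = np.asarray(y_codes, dtype=int)
    n = U.shape[0]
    if n == 0:
        raise ValueError("empty fusion training set")

    params = init_cnn(config)
    rng = np.random.default_rng(config.seed + 1)
    names = ["kernels", "conv_bias", "Wd", "bd"]
    m = {k: np.zeros_like(getattr(params, k)) for k in names}
    v = {k: np.zeros_like(getattr(params, k)) for k in names}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            B = idx.size
            mask = ((rng.random((B, config.n_filters)) >= config.dropout)
                    / max(1e-12, 1.0 - config.dropout))
            cache = _cnn_internals(U[idx], params, drop_mask=mask)
            w = cache["weights"]
            fused = fuse(P[idx], D[idx], w)
            losses.append(float(np.mean(-np.log(fused[np.arange(B), y[idx]] + 1e-12))))

            dfa = fused.copy()
            dfa[np.arange(B), y[idx]] -= 1.0
            dfa /= B                                     # dL/d(pre-softmax mix)
            dw = np.stack([(dfa * P[idx]).sum(1), (dfa * D[idx]).sum(1)], axis=1)
            dg = w * (dw - (dw * w).sum(axis=1, keepdims=True))

            grads = {
                "Wd": dg.T @ cache["dropped"],
                "bd": dg.sum(axis=0),
            }
            dgap = (dg @ params.Wd) * mask               # (B, C)
            dpool = np.repeat(dgap[:, None, :] / cache["Lp"], cache["Lp"], axis=1)
            dact = np.zeros_like(cache["pre"])
            C = params.kernels.shape[0]
            bi, pi, ci = np.meshgrid(np.arange(B), np.arange(cache["Lp"]),
                                     np.arange(C), indexing="ij")
            pos = 2 * pi + cache["arg"]                  # unpooled positions
            valid = pos < dact.shape[1]
            np.add.at(dact, (bi[valid], pos[valid], ci[valid]), dpool[valid])
            dpre = dact * (cache["pre"] > 0)
            grads["kernels"] = np.einsum("blc,blw->cw", dpre, cache["stack"])
            grads["conv_bias"] = dpre.sum(axis=(0, 1))

            step += 1
            for k in names:
                gr = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * gr
                v[k] = beta2 * v[k] + (1 - beta2) * gr * gr
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                getattr(params, k)[...] -= (
                    config.learning_rate * mhat / (np.sqrt(vhat) + eps))
        w_all = cnn_forward(U, params)
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)),
                     "mean_w2": float(w_all[:, 1].mean())})
    return params, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline-level wrapper
# ---------------------------------------------------------------------------

@dataclass
class FusionModel:
    """Frozen GRU + pruned tree + trained weight CNN, with a featurizer.

    ``featurizer`` maps a beat matrix (n, 250) to the spectral feature
    matrix the tree was trained on.
    """

    gru_params: GruParams
    tree: PrunedTree
    cnn: CnnParams
    featurizer: "callable"

    def branch_outputs(self, X: np.ndarray):
        from .gru import gru_predict
        P, h = gru_predict(self.gru_params, np.atleast_2d(X))
        D = self.tree.predict_dist(self.featurizer(np.atleast_2d(X)))
        U = build_fusion_input((P, h), self.gru_params)
        return P, D, U

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        P, D, U = self.branch_outputs(X)
        w = cnn_forward(U, self.cnn)
        return fuse(P, D, w)

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.asarray(self.gru_params.classes, dtype=object)[probs.argmax(1)]

    def fusion_weights(self, X: np.ndarray) -> np.ndarray:
        _P, _D, U = self.branch_outputs(X)
        return cnn_forward(U, self.cnn)


def train_fusion(valid_X: np.ndarray, valid_y, gru_params: GruParams,
                 tree: PrunedTree, featurizer,
                 config: FusionConfig | None = None
                 ) -> tuple[FusionModel, pd.DataFrame]:
    """Two-stage fusion training over a validation split.

    The GRU and tree are frozen; only the weight CNN is fit. Returns the
    assembled :class:`FusionModel` and the training trace (including the
    per-epoch mean learned tree weight W2).
    """
    from .gru import gru_predict
    X = np.atleast_2d(np.asarray(valid_X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty validation set")
    classes = gru_params.classes
    code = {c: i for i, c in enumerate(classes)}
    y = np.asarray([code[v] for v in np.asarray(valid_y)])
    P, h = gru_predict(gru_params, X)
    D = tree.predict_dist(featurizer(X))
    U = build_fusion_input((P, h), gru_params)
    cnn, trace = fit_fusion_cnn(U, P, D, y, config)
    return FusionModel(gru_params=gru_params, tree=tree, cnn=cnn,
                       featurizer=featurizer), trace
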