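"""GRU sequence classifier over 250-sample time-domain beats.

The recurrent cell is the standard gated recurrent unit:

    z_t = sigmoid(W_z . [h_{t-1}, x_t])
    r_t = sigmoid(W_r . [h_{t-1}, x_t])
    h~_t = tanh(W_h . [r_t * h_{t-1}, x_t])
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

The input layer frames the 250-sample beat into fixed-width input vectors
(default 10 samples per step, so 25 GRU steps per beat) after global
standardization; the final hidden state h_T feeds two fully connected
layers (tanh hidden, then the softmax class projection). Training minimizes mean cross-entropy
plus an L2 weight penalty (lambda / 2n) * sum(w^2), by mini-batch Adam with
gradients from manual backpropagation through time. Everything is NumPy;
gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GruParams",
    "TrainConfig",
    "gru_cell",
    "softmax",
    "cross_entropy",
    "loss",
    "gru_forward",
    "gru_predict",
    "train_gru",
    "save_params",
    "load_params",
]

CLASSES = ("N", "S", "V", "F")

_WEIGHT_NAMES = ("Wz", "Wr", "Wh", "W1", "W2")
_BIAS_NAMES = ("bz", "br", "bh", "b1", "b2")


@dataclass
class TrainConfig:
    """GRU training hyper-parameters.

    ``cell`` is the hidden size, ``l2_lambda`` the L2 coefficient (must lie
    in (0, 0.1]; set ``l2_lambda=0`` explicitly only for diagnostics), and
    ``aux_penalty_coeff`` an optional extra penalty on the norm of the first
    fully connected weight matrix (off by default).
    """

    cell: int = 64
    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 1e-3
    l2_lambda: float = 0.01
    aux_penalty_coeff: float = 0.0
    fc_size: int = 32
    frame_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.l2_lambda <= 0.1:
            raise ValueError("l2_lambda must lie in [0, 0.1]")
        if self.epochs < 1 or self.cell < 1:
            raise ValueError("epochs and cell must be >= 1")


@dataclass
class GruParams:
    """All learned parameters plus input normalization and the class alphabet.

    Gate matrices act on the concatenation ``[h_prev, x_t]`` (shape
    ``(H, H + D)``); ``W1/b1`` is the tanh hidden layer, ``W2/b2`` the class
    projection.
    """

    Wz: np.ndarray
    Wr: np.ndarray
    Wh: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    bh: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    x_mean: float = 0.0
    x_std: float = 1.0
    classes: tuple[str, ...] = CLASSES

    @property
    def hidden_size(self) -> int:
        return self.Wz.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wz.shape[1] - self.Wz.shape[0]

    def weight_arrays(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _WEIGHT_NAMES}

    def all_arrays(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _WEIGHT_NAMES + _BIAS_NAMES}

    def l2_sum(self) -> float:
        """Sum of squared weights (biases excluded)."""
        return float(sum(np.sum(w * w) for w in self.weight_arrays().values()))


def init_params(cell: int = 64, fc_size: int = 32, input_size: int = 1,
                n_classes: int = 4, seed: int = 0, scale: float = 0.08
                ) -> GruParams:
    """Small-uniform initialization of all weights (biases start at zero)."""
    rng = np.random.default_rng(seed)
    H, D, F, K = cell, input_size, fc_size, n_classes

    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    return GruParams(
        Wz=u(H, H + D), Wr=u(H, H + D), Wh=u(H, H + D),
        bz=np.zeros(H), br=np.zeros(H), bh=np.zeros(H),
        W1=u(F, H), b1=np.zeros(F), W2=u(K, F), b2=np.zeros(K),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def gru_cell(x_t: np.ndarray, h_prev: np.ndarray, params: GruParams
             ) -> np.ndarray:
    """One GRU step; accepts single vectors or batches (rows)."""
    x = np.atleast_2d(np.asarray(x_t, dtype=float))
    h = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if h.shape[1] != params.hidden_size or x.shape[1] != params.input_size:
        raise ValueError("input/hidden sizes do not match parameters")
    cat = np.hstack([h, x])
    z = _sigmoid(cat @ params.Wz.T + params.bz)
    r = _sigmoid(cat @ params.Wr.T + params.br)
    hcand = np.tanh(np.hstack([r * h, x]) @ params.Wh.T + params.bh)
    out = (1.0 - z) * h + z * hcand
    return out[0] if np.asarray(x_t).ndim == 1 else out


def softmax(V: np.ndarray) -> np.ndarray:
    """Shift-stable softmax along the last axis."""
    V = np.asarray(V, dtype=float)
    shifted = V - V.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_codes: np.ndarray) -> float:
    """Mean of ``-s_y + log sum_j exp(s_j)`` over the batch."""
    s = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.atleast_1d(np.asarray(y_codes, dtype=int))
    m = s.max(axis=1)
    lse = m + np.log(np.exp(s - m[:, None]).sum(axis=1))
    return float(np.mean(lse - s[np.arange(s.shape[0]), y]))


def loss(logits: np.ndarray, y_codes: np.ndarray, params: GruParams,
         config: TrainConfig, n: int | None = None) -> float:
    """Regularized cost: cross-entropy + (lambda/2n) sum w^2 + aux penalty."""
    s = np.atleast_2d(np.asarray(logits, dtype=float))
    if n is None:
        n = s.shape[0]
    c = cross_entropy(s, y_codes)
    c += config.l2_lambda / (2.0 * n) * params.l2_sum()
    if config.aux_penalty_coeff:
        c += config.aux_penalty_coeff * float(np.linalg.norm(params.W1))
    return c


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward_full(params: GruParams, X: np.ndarray, keep_cache: bool = False):
    """Run the GRU over whole sequences.

    ``X`` has shape (B, T); inputs are normalized with the stored mean/std.
    Returns (logits, h_T, o1, cache).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xn = (X - params.x_mean) / params.x_std
    B, L = Xn.shape
    D = params.input_size
    if L % D:
        raise ValueError(f"beat length {L} not divisible by frame size {D}")
    Xn = Xn.reshape(B, L // D, D)   # input layer: frame the scalar sequence
    T = L // D
    H = params.hidden_size
    h = np.zeros((B, H))
    cache = {"Z": [], "R": [], "Hc": [], "Hprev": []} if keep_cache else None
    for t in range(T):
        x = Xn[:, t]
        cat = np.hstack([h, x])
        z = _sigmoid(cat @ params.Wz.T + params.bz)
        r = _sigmoid(cat @ params.Wr.T + params.br)
        hcand = np.tanh(np.hstack([r * h, x]) @ params.Wh.T + params.bh)
        if keep_cache:
            cache["Z"].append(z)
            cache["R"].append(r)
            cache["Hc"].append(hcand)
            cache["Hprev"].append(h)
        h = (1.0 - z) * h + z * hcand
    a1 = h @ params.W1.T + params.b1
    o1 = np.tanh(a1)
    logits = o1 @ params.W2.T + params.b2
    if keep_cache:
        cache["Xn"] = Xn            # framed (B, T, D)
    return logits, h, o1, cache


def gru_forward(params: GruParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class logits and final hidden states for a beat matrix (B, 250)."""
    logits, h, _o1, _ = _forward_full(params, X)
    return logits, h


def gru_predict(params: GruParams, beat: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and final hidden state for one beat or a matrix."""
    arr = np.asarray(beat, dtype=float)
    one = arr.ndim == 1
    logits, h = gru_forward(params, arr)
    probs = softmax(logits)
    return (probs[0], h[0]) if one else (probs, h)


def _backward(params: GruParams, X: np.ndarray, y_codes: np.ndarray,
              config: TrainConfig) -> tuple[float, dict[str, np.ndarray]]:
    """Cost and analytic gradients for one mini-batch (BPTT)."""
    logits, hT, o1, cache = _forward_full(params, X, keep_cache=True)
    B = X.shape[0]
    H = params.hidden_size
    y = np.asarray(y_codes, dtype=int)

    cost = loss(logits, y, params, config, n=B)

    probs = softmax(logits)
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    g = {n: np.zeros_like(a) for n, a in params.all_arrays().items()}
    g["W2"] += dlogits.T @ o1
    g["b2"] += dlogits.sum(axis=0)
    do1 = dlogits @ params.W2
    da1 = do1 * (1.0 - o1 * o1)
    g["W1"] += da1.T @ hT
    g["b1"] += da1.sum(axis=0)
    dh = da1 @ params.W1

    Xn = cache["Xn"]
    for t in range(Xn.shape[1] - 1, -1, -1):
        z, r = cache["Z"][t], cache["R"][t]
        hcand, h_prev = cache["Hc"][t], cache["Hprev"][t]
        x = Xn[:, t]

        dz = dh * (hcand - h_prev)
        dhc = dh * z
        dh_prev = dh * (1.0 - z)

        dah = dhc * (1.0 - hcand * hcand)
        g["Wh"] += dah.T @ np.hstack([r * h_prev, x])
        g["bh"] += dah.sum(axis=0)
        dcat_h = dah @ params.Wh
        drh = dcat_h[:, :H]
        dr = drh * h_prev
        dh_prev += drh * r

        daz = dz * z * (1.0 - z)
        dar = dr * r * (1.0 - r)
        cat = np.hstack([h_prev, x])
        g["Wz"] += daz.T @ cat
        g["bz"] += daz.sum(axis=0)
        g["Wr"] += dar.T @ cat
        g["br"] += dar.sum(axis=0)
        dh_prev += daz @ params.Wz[:, :H] + dar @ params.Wr[:, :H]
        dh = dh_prev

    lam = config.l2_lambda / B
    for name in _WEIGHT_NAMES:
        g[name] += lam * getattr(params, name)
    if config.aux_penalty_coeff:
        norm = float(np.linalg.norm(params.W1))
        if norm > 0:
            g["W1"] += config.aux_penalty_coeff * params.W1 / norm
    return cost, g


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_gru(train_X: np.ndarray, train_y, valid_X: np.ndarray, valid_y,
              config: TrainConfig | None = None,
              classes: tuple[str, ...] = CLASSES
              ) -> tuple[GruParams, pd.DataFrame]:
    """Mini-batch Adam training; returns parameters and a per-epoch trace.

    The trace has columns ``epoch``, ``train_loss``, ``train_accuracy`` and
    ``valid_accuracy``. Fully reproducible from ``config.seed`` under
    single-threaded execution.
    """
    config = config or TrainConfig()
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    valid_X = np.atleast_2d(np.asarray(valid_X, dtype=float))
    if train_X.shape[0] == 0 or valid_X.shape[0] == 0:
        raise ValueError("empty dataset")
    code = {c: i for i, c in enumerate(classes)}
    ytr = np.asarray([code[v] for v in np.asarray(train_y)])
    yva = np.asarray([code[v] for v in np.asarray(valid_y)])

    if train_X.shape[1] % config.frame_size:
        raise ValueError("beat length must be divisible by frame_size")
    params = init_params(cell=config.cell, fc_size=config.fc_size,
                         input_size=config.frame_size,
                         n_classes=len(classes), seed=config.seed)
    params.classes = tuple(classes)
    params.x_mean = float(train_X.mean())
    params.x_std = float(train_X.std()) or 1.0

    rng = np.random.default_rng(config.seed + 1)
    names = list(params.all_arrays().keys())
    m = {n: np.zeros_like(a) for n, a in params.all_arrays().items()}
    v = {n: np.zeros_like(a) for n, a in params.all_arrays().items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rows = []
    n = train_X.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            cost, grads = _backward(params, train_X[idx], ytr[idx], config)
            losses.append(cost)
            step += 1
            for name in names:
                gr = grads[name]
                m[name] = beta1 * m[name] + (1 - beta1) * gr
                v[name] = beta2 * v[name] + (1 - beta2) * gr * gr
                mhat = m[name] / (1 - beta1 ** step)
                vhat = v[name] / (1 - beta2 ** step)
                getattr(params, name)[...] -= (
                    config.learning_rate * mhat / (np.sqrt(vhat) + eps))
        tr_logits, _ = gru_forward(params, train_X)
        va_logits, _ = gru_forward(params, valid_X)
        rows.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": float(np.mean(tr_logits.argmax(1) == ytr)),
            "valid_accuracy": float(np.mean(va_logits.argmax(1) == yva)),
        })
    return params, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization: npz archive with a JSON manifest
# ---------------------------------------------------------------------------

def save_params(path: str | Path, params: GruParams,
                config: TrainConfig | None = None) -> None:
    """Save parameters as an npz archive plus an embedded JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = params.all_arrays()
    np.savez(path, **arrays)
    manifest = {
        "classes": list(params.classes),
        "x_mean": params.x_mean,
        "x_std": params.x_std,
        "shapes": {k: list(a.shape) for k, a in arrays.items()},
        "config": asdict(config) if config else None,
    }
    with zipfile.ZipFile(path if path.suffix == ".npz" else f"{path}.npz",
                         "a") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))


def load_params(path: str | Path) -> GruParams:
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = Path(f"{path}.npz")
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files
                  if k in _WEIGHT_NAMES + _BIAS_NAMES}
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
    return GruParams(**arrays, x_mean=manifest["x_mean"],
                     x_std=manifest["x_std"],
                     classes=tuple(manifest["classes"]))
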