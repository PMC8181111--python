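"""Reading and writing annotated ECG records and beat matrices.

Supports a WFDB-dialect record triplet (``.hea`` header, format-212 ``.dat``
signal, MIT ``.atr`` annotations) plus flat CSV beat matrices, and maps beat
annotation symbols onto the five AAMI heartbeat classes N/S/V/F/Q.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EcgRecord",
    "AAMI_CLASSES",
    "BEAT_SYMBOLS",
    "AAMI_MAP",
    "NonBeatSymbolError",
    "map_aami",
    "read_record",
    "write_record",
    "read_beat_csv",
    "write_beat_csv",
]

#: The five AAMI heartbeat classes. Q (unclassifiable/paced) is discarded
#: downstream before any training or evaluation.
AAMI_CLASSES = ("N", "S", "V", "F", "Q")

#: Standard PhysioNet beat-annotation symbols (QRS-marking annotations).
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnE/fQ?")

#: Canonical symbol -> AAMI class mapping:
#: N <- {N, L, R, e, j}  (normal, bundle-branch block, escape)
#: S <- {A, a, J, S}     (supraventricular ectopic)
#: V <- {V, E}           (ventricular ectopic)
#: F <- {F}              (fusion of ventricular and normal)
#: Q <- {/, f, Q}        (paced, fusion of paced and normal, unclassifiable)
AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}


class NonBeatSymbolError(ValueError):
    """Raised when an annotation symbol does not mark a beat (rhythm/quality)."""


def map_aami(symbol: str) -> str:
    """Map a beat annotation symbol to its AAMI class.

    Unknown *beat* symbols map to Q (unclassifiable); non-beat symbols
    (rhythm change, signal quality, comments) raise :class:`NonBeatSymbolError`
    so the caller can skip them.
    """
    if symbol not in BEAT_SYMBOLS:
        raise NonBeatSymbolError(f"{symbol!r} is not a beat annotation symbol")
    return AAMI_MAP.get(symbol, "Q")


@dataclass
class EcgRecord:
    """An annotated multi-lead ECG signal at a fixed sampling rate.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_leads)
        Amplitudes in millivolts.
    fs : float
        Sampling rate in Hz (> 0).
    lead_names : list of str
    annotations : list of (int, str)
        ``(sample_index, symbol)`` pairs; the index marks the R-peak sample
        (0-based).
    """

    signal: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] < self.signal.shape[1]:
            # accept (n_leads, n_samples) input from 1-D promotions
            if self.signal.shape[0] <= 16:
                self.signal = self.signal.T
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.signal.shape[1])]
        if len(self.lead_names) != self.signal.shape[1]:
            raise ValueError("lead_names length does not match signal leads")
        n = self.signal.shape[0]
        for idx, _sym in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    def lead(self, i: int = 0) -> np.ndarray:
        """Return one lead as a 1-D array (default: first lead)."""
        return self.signal[:, i]


# ---------------------------------------------------------------------------
# WFDB dialect: .hea / format-212 .dat / MIT .atr
# ---------------------------------------------------------------------------

# MIT annotation code table (code <-> mnemonic), QRS and non-QRS codes.
_ANN_CODE_TO_SYM = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_ANN_SYM_TO_CODE = {v: k for k, v in _ANN_CODE_TO_SYM.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _parse_gain(tok: str) -> tuple[float, int | None]:
    """Parse a header gain token like ``200``, ``200(1024)/mV``."""
    if "/" in tok:
        tok = tok.split("/", 1)[0]
    baseline = None
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline


def read_record(path: str | Path) -> EcgRecord:
    """Read a WFDB-dialect record (``.hea`` + format-212 ``.dat`` [+ ``.atr``]).

    ``path`` is the record path without extension. Raises ``FileNotFoundError``
    for missing files and ``ValueError`` for malformed headers.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"malformed header line in {hea}: {lines[0]!r}")
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if fs <= 0:
        raise ValueError(f"non-positive sampling rate in {hea}: {fs}")

    gains, baselines, adc_zeros, names, dat_name, fmt = [], [], [], [], None, None
    for i in range(n_sig):
        tok = lines[1 + i].split()
        if dat_name is None:
            dat_name = tok[0]
        elif tok[0] != dat_name:
            raise ValueError("multi-file records are not supported")
        f = int("".join(c for c in tok[1] if c.isdigit()) or "212")
        if fmt is None:
            fmt = f
        gain, baseline = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, None)
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        gains.append(gain)
        baselines.append(baseline if baseline is not None else adc_zero)
        adc_zeros.append(adc_zero)
        names.append(tok[8] if len(tok) > 8 else f"lead{i}")
    if fmt != 212:
        raise ValueError(f"unsupported signal format {fmt} (only 212)")

    dat = path.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    adc = _read_212(dat.read_bytes(), n_sig * n_samples)
    adc = adc[: n_sig * n_samples].reshape(n_samples, n_sig)
    phys = (adc - np.asarray(baselines)) / np.asarray(gains)

    annotations: list[tuple[int, str]] = []
    atr = path.with_suffix(".atr")
    if atr.exists():
        annotations = _read_annotations(atr.read_bytes())
        for idx, _ in annotations:
            if not 0 <= idx < n_samples:
                raise ValueError(f"annotation index {idx} outside record")
    return EcgRecord(signal=phys, fs=fs, lead_names=names, annotations=annotations)


def _read_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def _write_212(adc: np.ndarray) -> bytes:
    flat = np.asarray(adc, dtype=np.int32).reshape(-1)
    if flat.min() < -2048 or flat.max() > 2047:
        raise ValueError("ADC values out of 12-bit range for format 212")
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    flat = np.where(flat < 0, flat + 4096, flat)
    a, b = flat[0::2], flat[1::2]
    out = np.empty((a.size, 3), dtype=np.uint8)
    out[:, 0] = a & 0xFF
    out[:, 1] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[:, 2] = b & 0xFF
    return out.tobytes()


def _read_annotations(raw: bytes) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            (long_skip,) = struct.unpack("<i", raw[i + 2:i + 4] + raw[i:i + 2])
            i += 4
            t += long_skip
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += interval
        out.append((t, _ANN_CODE_TO_SYM.get(code, "?")))
    return out


def _write_annotations(annotations: Sequence[tuple[int, str]]) -> bytes:
    parts: list[bytes] = []
    prev = 0
    for idx, sym in sorted(annotations):
        code = _ANN_SYM_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"cannot encode annotation symbol {sym!r}")
        delta = idx - prev
        if delta < 0:
            raise ValueError("annotation indices must be sorted")
        if delta > 1023:
            hi, lo = delta >> 16, delta & 0xFFFF
            parts.append(struct.pack("<HHH", (_SKIP << 10), hi, lo))
            delta = 0
        parts.append(struct.pack("<H", (code << 10) | delta))
        prev = idx
    parts.append(struct.pack("<H", 0))
    return b"".join(parts)


def write_record(path: str | Path, record: EcgRecord, gain: float = 200.0,
                 baseline: int = 1024) -> None:
    """Write *record* as a WFDB-dialect triplet (.hea / .dat format 212 / .atr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name
    adc = np.rint(record.signal * gain + baseline).astype(np.int32)
    if adc.min() < -2048 or adc.max() > 2047:
        raise ValueError("signal exceeds 12-bit ADC range at this gain")
    lines = [f"{name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for j in range(record.n_leads):
        lines.append(
            f"{name}.dat 212 {gain:g}({baseline})/mV 12 {baseline} "
            f"{adc[0, j]} 0 0 {record.lead_names[j]}"
        )
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    (path.parent / f"{name}.dat").write_bytes(_write_212(adc.reshape(-1)))
    if record.annotations:
        path.with_suffix(".atr").write_bytes(_write_annotations(record.annotations))


# ---------------------------------------------------------------------------
# CSV beat matrices (one row = 250 amplitudes + label column, header required)
# ---------------------------------------------------------------------------

def write_beat_csv(path: str | Path, beats: np.ndarray,
                   labels: Sequence[str]) -> None:
    """Write a beat matrix: columns ``s0..s{L-1},label`` with a header row."""
    beats = np.asarray(beats, dtype=float)
    if beats.ndim != 2 or len(labels) != beats.shape[0]:
        raise ValueError("beats must be 2-D with one label per row")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"s{i}" for i in range(beats.shape[1])] + ["label"])
        for row, lab in zip(beats, labels):
            w.writerow([f"{v:.9g}" for v in row] + [lab])


def read_beat_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a beat matrix CSV; returns ``(beats, labels)``."""
    path = Path(path)
    with path.open() as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[-1] != "label" or not header[0].startswith("s"):
            raise ValueError(f"{path}: expected header 's0..,label'")
        rows, labels = [], []
        for row in r:
            if not row:
                continue
            rows.append([float(v) for v in row[:-1]])
            labels.append(row[-1])
    return np.asarray(rows, dtype=float), np.asarray(labels)
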