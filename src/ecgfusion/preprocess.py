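"""Signal conditioning and beat extraction.

Denoising uses a discrete wavelet transform with universal-threshold
shrinkage of the detail coefficients. R peaks are located with the classical
Pan-Tompkins pipeline (band-pass, derivative, squaring, moving-window
integration, adaptive dual thresholds with search-back). Beats are cut as
fixed 250-sample windows, 108 samples before and 142 after the R apex at
360 Hz, and labeled from the record's annotations mapped to AAMI classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .io import EcgRecord, NonBeatSymbolError, map_aami

__all__ = [
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "DenoiseConfig",
    "Beat",
    "BeatDataset",
    "dwt_denoise",
    "detect_r_peaks",
    "segment_beats",
]

#: Beat window split around the R apex at 360 Hz: 108 pre + 142 post = 250.
PRE_SAMPLES = 108
POST_SAMPLES = 142
BEAT_LENGTH = PRE_SAMPLES + POST_SAMPLES


@dataclass
class DenoiseConfig:
    """Wavelet denoiser settings (db6 / level 6 / universal soft threshold)."""

    wavelet_name: str = "db6"
    decomposition_level: int = 6
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError(f"threshold_mode must be 'soft' or 'hard'")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}")


def dwt_denoise(signal: np.ndarray, config: DenoiseConfig | None = None) -> np.ndarray:
    """Wavelet-shrinkage denoising; output has the same length as the input.

    The noise scale is estimated from the finest detail band via the median
    absolute deviation, and the universal threshold sigma*sqrt(2 ln n) is
    applied to every detail band (approximation coefficients are kept).
    """
    config = config or DenoiseConfig()
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 2 ** config.decomposition_level:
        raise ValueError(
            f"signal length {n} too short for level {config.decomposition_level}")
    coeffs = pywt.wavedec(x, config.wavelet_name, level=config.decomposition_level)
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail - np.median(detail))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    if thr > 0:
        coeffs[1:] = [pywt.threshold(c, thr, mode=config.threshold_mode)
                      for c in coeffs[1:]]
    return pywt.waverec(coeffs, config.wavelet_name)[:n]


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------

def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Locate R peaks with the Pan-Tompkins algorithm.

    Pipeline: 5-15 Hz band-pass -> five-point derivative -> squaring ->
    150 ms moving-window integration -> adaptive dual thresholds (signal and
    noise level estimates) with search-back at half threshold, plus a 200 ms
    refractory period. Returned indices are strictly increasing R-apex
    positions refined on the band-passed signal.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative (zero-phase via symmetric kernel)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) / 8.0, mode="same")
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive dual thresholds on the integrated waveform
    spki = float(np.max(integ[: int(2 * fs)]) / 3.0)
    npki = float(np.mean(integ[: int(2 * fs)]) / 2.0)
    qrs: list[int] = []
    rr_hist: list[float] = []
    last = -10 * fs

    def _accept(p: int, peak_val: float) -> None:
        nonlocal spki, last
        spki = 0.125 * peak_val + 0.875 * spki
        if qrs:
            rr_hist.append(p - qrs[-1])
            if len(rr_hist) > 8:
                rr_hist.pop(0)
        qrs.append(p)
        last = p

    for p in cand:
        thr1 = npki + 0.25 * (spki - npki)
        pv = integ[p]
        if pv > thr1 and p - last >= refractory:
            # search-back: a long gap may hide a missed beat above thr1/2
            if rr_hist and qrs and (p - qrs[-1]) > 1.66 * np.mean(rr_hist):
                lo, hi = qrs[-1] + refractory, p - refractory
                if hi > lo:
                    seg = cand[(cand > lo) & (cand < hi)]
                    if seg.size:
                        best = seg[np.argmax(integ[seg])]
                        if integ[best] > 0.5 * thr1:
                            _accept(int(best), float(integ[best]))
            _accept(int(p), float(pv))
        else:
            npki = 0.125 * pv + 0.875 * npki

    # refine each detection to the R apex on the band-passed signal
    half = int(round(0.100 * fs))
    refined: list[int] = []
    for p in qrs:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        r = lo + int(np.argmax(bp[lo:hi]))
        if not refined or r - refined[-1] >= refractory:
            refined.append(r)
        elif bp[r] > bp[refined[-1]]:
            refined[-1] = r
    return np.asarray(refined, dtype=int)


# ---------------------------------------------------------------------------
# Beat segmentation
# ---------------------------------------------------------------------------

@dataclass
class Beat:
    """A fixed-length labeled beat window (250 samples, R apex at index 108)."""

    samples: np.ndarray
    r_index_global: int
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != BEAT_LENGTH:
            raise ValueError(f"beat must have {BEAT_LENGTH} samples")
        if self.label not in ("N", "S", "V", "F"):
            raise ValueError(f"invalid training label {self.label!r}")


@dataclass
class BeatDataset:
    """A collection of labeled beats with consistent class tallies."""

    beats: list[Beat] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(b.label for b in self.beats))

    def __len__(self) -> int:
        return len(self.beats)

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, y)``: beats stacked row-wise and their labels."""
        if not self.beats:
            return np.empty((0, BEAT_LENGTH)), np.empty((0,), dtype=object)
        X = np.stack([b.samples for b in self.beats])
        y = np.asarray([b.label for b in self.beats], dtype=object)
        return X, y


def segment_beats(record: EcgRecord, r_peaks: np.ndarray | list[int],
                  lead: int = 0, label_tolerance_s: float = 0.050) -> BeatDataset:
    """Cut 250-sample windows around R peaks and attach AAMI labels.

    Each R peak with full window support gets the window ``[R-108, R+142)``.
    The label comes from the nearest beat annotation within +-50 ms of the R
    position; beats without such an annotation, beats mapping to class Q and
    beats overlapping the record boundaries are dropped.
    """
    if int(round(record.fs)) != 360:
        raise ValueError("segmentation requires fs = 360 Hz (resample first)")
    x = record.lead(lead)
    n = x.size
    tol = int(round(label_tolerance_s * record.fs))

    ann = sorted(record.annotations)
    ann_idx = np.asarray([a[0] for a in ann], dtype=int)
    ann_sym = [a[1] for a in ann]

    beats: list[Beat] = []
    for r in sorted(int(r) for r in r_peaks):
        if not 0 <= r < n:
            raise ValueError(f"R index {r} outside record")
        lo, hi = r - PRE_SAMPLES, r + POST_SAMPLES
        if lo < 0 or hi > n:
            continue
        if ann_idx.size == 0:
            continue
        j = int(np.argmin(np.abs(ann_idx - r)))
        if abs(int(ann_idx[j]) - r) > tol:
            continue
        try:
            label = map_aami(ann_sym[j])
        except NonBeatSymbolError:
            continue
        if label == "Q":
            continue
        beats.append(Beat(samples=x[lo:hi].copy(), r_index_global=r, label=label))
    return BeatDataset(beats=beats)
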