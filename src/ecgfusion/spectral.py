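"""Frequency-domain beat features.

A 250-sample beat has a length-250 DFT; by conjugate symmetry of real
signals the first 125 magnitude bins carry all the information, so the
unsegmented feature vector is ``|X_k|, k = 0..124``. The segmented variant
anchors three time sub-windows on the QRS complex (P-wave band, QRS band,
T-wave band), takes the DFT of each sub-window separately and concatenates
the first ``ceil(len/2)`` magnitudes of each in P, QRS, T order — again 125
components for the default partition (45 + 18 + 62). A frequency-slice
variant (slicing the full-beat spectrum at the partition boundaries mapped
to bins) is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

__all__ = [
    "SubwavePartition",
    "SpectralFeatureSet",
    "dft_magnitude",
    "default_partition",
    "subband_features",
    "band_prefix",
    "beat_features",
    "dataset_features",
]

BEAT_LENGTH = 250
HALF_SPECTRUM = 125


@dataclass(frozen=True)
class SubwavePartition:
    """Half-open sample ranges for the P, QRS and T sub-windows of a beat."""

    p_window: tuple[int, int]
    qrs_window: tuple[int, int]
    t_window: tuple[int, int]

    def __post_init__(self) -> None:
        p, q, t = self.p_window, self.qrs_window, self.t_window
        if not (0 == p[0] <= p[1] == q[0] <= q[1] == t[0] <= t[1] == BEAT_LENGTH):
            raise ValueError("windows must be ordered, disjoint and cover [0, 250)")

    @property
    def windows(self) -> dict[str, tuple[int, int]]:
        return {"P": self.p_window, "QRS": self.qrs_window, "T": self.t_window}


def default_partition() -> SubwavePartition:
    """QRS window = R apex (sample 108) +- ~50 ms: [90, 126); P before, T after.

    At 360 Hz the QRS window spans 36 samples = 100 ms, matching the energy
    concentration of ventricular depolarization; the P band is [0, 90) and
    the T band [126, 250).
    """
    return SubwavePartition(p_window=(0, 90), qrs_window=(90, 126),
                            t_window=(126, 250))


@dataclass
class SpectralFeatureSet:
    """Per-beat DFT magnitude features with per-component provenance.

    ``features`` is ``(n_beats, n_components)``; ``band_index`` records for
    each component the source window name ("full", "P", "QRS" or "T") and the
    frequency-bin index within that window's DFT.
    """

    features: np.ndarray
    band_index: list[tuple[str, int]]
    segmented: bool

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if np.any(self.features < 0):
            raise ValueError("magnitudes must be non-negative")
        if len(self.band_index) != self.features.shape[1]:
            raise ValueError("band_index length must equal feature dimension")
        if not self.segmented and self.features.shape[1] > HALF_SPECTRUM:
            # a full unsegmented set has exactly 125 components; prefixes fewer
            raise ValueError(
                f"unsegmented features cannot exceed {HALF_SPECTRUM} components")

    @property
    def n_components(self) -> int:
        return self.features.shape[1]


def dft_magnitude(beat: np.ndarray) -> np.ndarray:
    """First 125 DFT magnitude bins of a real 250-sample beat.

    Conjugate symmetry (bin ``k`` and bin ``250-k`` are conjugates) makes
    the remaining bins redundant.
    """
    x = np.asarray(beat, dtype=float)
    if x.ndim == 1:
        if x.size != BEAT_LENGTH:
            raise ValueError(f"beat must have {BEAT_LENGTH} samples")
        return np.abs(np.fft.fft(x))[:HALF_SPECTRUM]
    if x.shape[1] != BEAT_LENGTH:
        raise ValueError(f"beats must have {BEAT_LENGTH} samples")
    return np.abs(np.fft.fft(x, axis=1))[:, :HALF_SPECTRUM]


def subband_features(beat: np.ndarray, partition: SubwavePartition | None = None,
                     mode: str = "time") -> SpectralFeatureSet:
    """QRS-anchored sub-band magnitude features of one beat or a beat matrix.

    ``mode="time"`` (default) DFTs each time sub-window separately and keeps
    the first ``ceil(len/2)`` magnitudes of each; ``mode="slice"`` slices the
    full-beat half spectrum at the partition boundaries scaled to bins.
    """
    partition = partition or default_partition()
    X = np.atleast_2d(np.asarray(beat, dtype=float))
    if X.shape[1] != BEAT_LENGTH:
        raise ValueError(f"beats must have {BEAT_LENGTH} samples")

    blocks: list[np.ndarray] = []
    index: list[tuple[str, int]] = []
    if mode == "time":
        for name, (lo, hi) in partition.windows.items():
            ln = hi - lo
            if ln < 4:
                raise ValueError(f"degenerate {name} window of length {ln}")
            keep = ceil(ln / 2)
            blocks.append(np.abs(np.fft.fft(X[:, lo:hi], axis=1))[:, :keep])
            index.extend((name, k) for k in range(keep))
    elif mode == "slice":
        mags = np.abs(np.fft.fft(X, axis=1))[:, :HALF_SPECTRUM]
        for name, (lo, hi) in partition.windows.items():
            blo = lo * HALF_SPECTRUM // BEAT_LENGTH
            bhi = hi * HALF_SPECTRUM // BEAT_LENGTH
            blocks.append(mags[:, blo:bhi])
            index.extend((name, k) for k in range(blo, bhi))
    else:
        raise ValueError(f"unknown sub-band mode {mode!r}")
    return SpectralFeatureSet(features=np.hstack(blocks), band_index=index,
                              segmented=True)


def band_prefix(features: SpectralFeatureSet, k: int) -> SpectralFeatureSet:
    """Keep the first *k* components of an unsegmented feature set."""
    if features.segmented:
        raise ValueError("band_prefix applies to unsegmented features")
    if not 1 <= k <= features.n_components:
        raise ValueError(f"k must be in [1, {features.n_components}]")
    return SpectralFeatureSet(features=features.features[:, :k],
                              band_index=features.band_index[:k],
                              segmented=False)


def beat_features(X: np.ndarray, segmented: bool = True,
                  partition: SubwavePartition | None = None,
                  mode: str = "time", normalize: bool = False) -> SpectralFeatureSet:
    """Feature set for a beat matrix: segmented sub-bands or plain half-spectrum.

    With ``normalize=True`` each beat's feature vector is scaled to unit
    Euclidean norm.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if segmented:
        fset = subband_features(X, partition, mode=mode)
    else:
        mags = dft_magnitude(X)
        fset = SpectralFeatureSet(features=mags,
                                  band_index=[("full", k) for k in range(HALF_SPECTRUM)],
                                  segmented=False)
    if normalize:
        norms = np.linalg.norm(fset.features, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        fset.features = fset.features / norms
    return fset


# alias used by the pipeline layers
dataset_features = beat_features
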