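"""Synthetic annotated ECG strips with class-dependent beat morphology.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on a 250-sample
window anchored with the R apex at sample 108 (the segmentation convention
used throughout the package). Class rules:

* ``N`` — canonical P-QRS-T morphology;
* ``S`` — attenuated/absent P bump; the preceding RR interval is shortened
  when strips are assembled (premature supraventricular beat);
* ``V`` — widened QRS (>= 2x the normal width), inverted T, no P wave;
* ``F`` — element-wise mean of the N and V templates (fusion beat).

Records add baseline wander, broadband Gaussian noise and an optional
powerline tone, and carry ground-truth R positions and AAMI labels. The
generator is a pure function of its configuration (seed-reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import EcgRecord

__all__ = [
    "BEAT_LENGTH",
    "R_ANCHOR",
    "BUMP_PARAMS",
    "SyntheticConfig",
    "make_beat",
    "make_record",
    "make_record_at_snr",
    "noise_sd_for_snr",
]

#: Fixed beat window length in samples (at 360 Hz: ~0.69 s).
BEAT_LENGTH = 250
#: Index of the R apex inside the beat window.
R_ANCHOR = 108

# Per-class bump parameters: (center offset from R in samples @360 Hz,
# width sigma in samples, amplitude in mV). F is derived, not listed.
BUMP_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "N": {
        "P": (-55.0, 9.0, 0.15),
        "Q": (-10.0, 3.0, -0.12),
        "R": (0.0, 5.0, 1.00),
        "S": (10.0, 3.5, -0.25),
        "T": (65.0, 16.0, 0.35),
    },
    "S": {
        "P": (-45.0, 9.0, 0.02),   # attenuated, nearly absent P
        "Q": (-10.0, 3.0, -0.12),
        "R": (0.0, 5.0, 0.95),
        "S": (10.0, 3.5, -0.25),
        "T": (60.0, 15.0, 0.30),
    },
    "V": {
        "P": (-55.0, 9.0, 0.0),    # absent P
        "Q": (-18.0, 8.0, -0.20),  # widened QRS complex (sigma >= 2x N)
        "R": (0.0, 12.0, 1.10),
        "S": (20.0, 9.0, -0.40),
        "T": (70.0, 18.0, -0.35),  # inverted T
    },
}


@dataclass
class SyntheticConfig:
    """Configuration for a synthetic annotated strip.

    ``class_mix`` is the probability vector over (N, S, V, F);
    ``heart_rate_bpm`` and ``heart_rate_jitter`` set the mean RR interval and
    its relative jitter; ``noise_sd`` is the SD of additive white noise (mV);
    ``baseline_amp`` the baseline-wander amplitude (mV); ``powerline_hz``
    adds a mains tone when not None.
    """

    fs: float = 360.0
    n_beats: int = 100
    class_mix: Sequence[float] = (0.7, 0.1, 0.15, 0.05)
    heart_rate_bpm: float = 72.0
    heart_rate_jitter: float = 0.05
    noise_sd: float = 0.0
    baseline_amp: float = 0.05
    baseline_hz: float = 0.25
    powerline_hz: float | None = None
    powerline_amp: float = 0.01
    amplitude_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("class_mix must be 4 non-negative values summing to 1")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def _template(label: str, fs: float, scale: float) -> np.ndarray:
    """Noise-free class template with a global amplitude scale."""
    ratio = fs / 360.0
    n = int(round(BEAT_LENGTH * ratio))
    anchor = R_ANCHOR * ratio
    t = np.arange(n, dtype=float)
    sig = np.zeros(n)
    for center, sigma, amp in BUMP_PARAMS[label].values():
        c = anchor + center * ratio
        s = sigma * ratio
        sig += amp * np.exp(-0.5 * ((t - c) / s) ** 2)
    return scale * sig


def make_beat(label: str, fs: float = 360.0, seed: int = 0,
              amplitude_jitter: float = 0.03) -> np.ndarray:
    """Generate one noise-free beat window for an AAMI class.

    The seed drives a small per-beat global amplitude jitter. The fusion
    class F is constructed as the element-wise mean of the N and V beats
    drawn with the same seed.
    """
    if label == "F":
        return 0.5 * (make_beat("N", fs, seed, amplitude_jitter)
                      + make_beat("V", fs, seed, amplitude_jitter))
    if label not in BUMP_PARAMS:
        raise ValueError(f"unknown beat label {label!r}")
    rng = np.random.default_rng(seed)
    scale = max(0.1, 1.0 + amplitude_jitter * rng.standard_normal())
    return _template(label, fs, scale)


def noise_sd_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """Noise SD giving the requested SNR (dB) against a clean signal's power."""
    power = float(np.mean(np.square(clean)))
    return float(np.sqrt(power / 10.0 ** (snr_db / 10.0)))


# representative annotation symbol per class (used when writing fixtures)
_CLASS_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F"}
_CLASSES = ("N", "S", "V", "F")


def make_record(config: SyntheticConfig) -> tuple[EcgRecord, np.ndarray, np.ndarray]:
    """Assemble an annotated multi-beat strip.

    Returns ``(record, r_positions, labels)`` where ``r_positions`` are the
    ground-truth R-apex sample indices and ``labels`` the AAMI class of each
    beat. The record also carries the same ground truth as annotations using
    one representative symbol per class.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    ratio = fs / 360.0
    n = config.n_beats

    labels = rng.choice(_CLASSES, size=n, p=np.asarray(config.class_mix, float))

    mean_rr = 60.0 / config.heart_rate_bpm * fs
    rr = mean_rr * (1.0 + config.heart_rate_jitter * rng.standard_normal(n))
    # premature supraventricular beats arrive early: shorten the preceding RR
    rr[labels == "S"] *= 0.7
    rr = np.maximum(rr, 0.30 * fs)  # refractory floor

    r_pos = np.cumsum(rr).astype(int) + int(R_ANCHOR * ratio)
    pre = int(round(R_ANCHOR * ratio))
    post = int(round(BEAT_LENGTH * ratio)) - pre
    total = r_pos[-1] + post + int(0.2 * fs)

    signal = np.zeros(total)
    beat_seeds = rng.integers(0, 2**31 - 1, size=n)
    for r, lab, s in zip(r_pos, labels, beat_seeds):
        beat = make_beat(str(lab), fs, int(s), config.amplitude_jitter)
        lo = r - pre
        signal[lo:lo + beat.size] += beat

    t = np.arange(total) / fs
    if config.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.baseline_amp * np.sin(2 * np.pi * config.baseline_hz * t + phase)
    if config.powerline_hz is not None:
        signal += config.powerline_amp * np.sin(2 * np.pi * config.powerline_hz * t)
    if config.noise_sd > 0:
        signal += config.noise_sd * rng.standard_normal(total)

    annotations = [(int(r), _CLASS_SYMBOL[str(lab)]) for r, lab in zip(r_pos, labels)]
    record = EcgRecord(signal=signal[:, None], fs=fs, lead_names=["MLII"],
                       annotations=annotations)
    return record, r_pos, np.asarray(labels, dtype=object)


def make_record_at_snr(config: SyntheticConfig, snr_db: float
                       ) -> tuple[EcgRecord, np.ndarray, np.ndarray]:
    """Like :func:`make_record`, but with white noise set to a target SNR.

    The clean strip (no noise, no baseline wander) is generated first to
    measure signal power, then the record is regenerated from the same seed
    with the matching noise standard deviation.
    """
    from dataclasses import replace

    clean_cfg = replace(config, noise_sd=0.0, baseline_amp=0.0)
    clean, _r, _l = make_record(clean_cfg)
    sd = noise_sd_for_snr(clean.lead(0), snr_db)
    return make_record(replace(config, noise_sd=sd))
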