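"""Synthesize an annotated ECG strip and locate its R peaks.

Builds a 200-beat strip at 10 dB SNR, denoises it, runs Pan-Tompkins
detection and scores the detections against the generator's ground truth.
"""

import numpy as np

from ecgfusion import (SyntheticConfig, detect_r_peaks, dwt_denoise,
                       make_record_at_snr, r_peak_detection_stats)

config = SyntheticConfig(n_beats=200, heart_rate_bpm=72.0, seed=1)
record, r_truth, labels = make_record_at_snr(config, snr_db=10.0)
counts = dict(zip(*np.unique(labels, return_counts=True)))
print(f"strip: {record.n_samples} samples at {record.fs:g} Hz, "
      f"{len(r_truth)} beats, classes {counts}")

denoised = dwt_denoise(record.lead(0))
detected = detect_r_peaks(denoised, record.fs)
stats = r_peak_detection_stats(r_truth, detected, record.fs, tol_s=0.050)

print(f"detected {stats['n_detected']} peaks, {stats['tp']} matched within 50 ms")
print(f"sensitivity {stats['sensitivity']:.2f}%  "
      f"positive predictivity {stats['positive_predictivity']:.2f}%")
print("Both near 100% means essentially every heartbeat was found, with no"
      " spurious detections, despite the added noise.")
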