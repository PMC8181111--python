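# Methods

This note documents the models, defaults and numerical choices behind
`ecgfusion`, and what the synthetic benchmark does and does not show.

## Pipeline overview

A record is denoised, R peaks are located, beats are cut as fixed windows
and labeled, and two classifiers are trained on disjoint views of the same
beats — a GRU on the time-domain window, a CART on DFT sub-band magnitudes
— before a learned per-beat convex combination fuses their outputs.

## Preprocessing

**Denoising.** Discrete wavelet shrinkage: db6 at level 6, universal
threshold σ√(2 ln n) with σ estimated from the median absolute deviation of
the finest detail band (MAD/0.6745), soft thresholding, approximation
coefficients untouched. db6/level 6 is a common choice for 360 Hz ECG: at
that depth the approximation band sits below ~3 Hz, so QRS energy stays in
the retained details while broadband noise is shrunk. The denoiser is
linear-phase in effect (full decomposition/reconstruction), output length
equals input length.

**R-peak detection.** Classical Pan–Tompkins: zero-phase 5–15 Hz Butterworth
band-pass, five-point derivative, squaring, 150 ms moving-window
integration, then adaptive dual thresholds (running signal and noise level
estimates, threshold = noise + 0.25·(signal − noise)) with search-back at
half threshold when an RR gap exceeds 1.66× the running RR average, and a
200 ms refractory period. Detections are refined to the apex of the
band-passed signal within ±100 ms. Using a zero-phase filter removes the
need for group-delay compensation.

**Segmentation.** The beat window is 250 samples at 360 Hz: 108 samples
(0.300 s) before the R apex and 142 (≈0.394 s) after. A nominal 0.3 s + 0.4 s
split would give 252 samples; we keep the canonical 250 and bias the
rounding to the post-R side, where the T wave is wide and a two-sample loss
is immaterial. Labels come from the nearest beat annotation within ±50 ms
of the R position; beats without a label, beats overlapping the record
boundary, and Q-class (paced/unclassifiable) beats are dropped. Detected
peaks are used for labeling only when no annotations exist.

## Spectral features

The 250-point DFT of a real beat is conjugate-symmetric, so bins 0–124
carry all information; the unsegmented feature vector is those 125
magnitudes. The segmented variant partitions the *time* window at
QRS-anchored boundaries — P = [0, 90), QRS = [90, 126) (R ± ~50 ms),
T = [126, 250) — DFTs each sub-window separately and concatenates the first
⌈len/2⌉ magnitudes of each (45 + 18 + 62 = 125). DFT-of-time-sub-windows
was chosen over slicing the full-beat spectrum because it ties each feature
block to one physiological wave; the frequency-slice alternative is
available via `mode="slice"` for comparison. Magnitudes only (phase
discarded); no normalization by default, per-beat unit-energy normalization
optional.

## Decision-tree branch

From-scratch CART: splits maximize Gini impurity decrease over all
attributes with thresholds at midpoints of consecutive distinct sorted
values; ties break to the lowest attribute index, then the lowest
threshold, making training fully deterministic. Leaves store empirical
class distributions. Pruning is weakest-link cost-complexity pruning with
C(T) = training misclassification count and |T| = leaf count; all nodes
attaining the minimal link value g(t) are collapsed together, yielding a
nested chain with strictly increasing critical α. Correctness of both split
selection and the chain is checked in tests against exhaustive enumeration
(all splits; all pruned subtrees for small trees) and against scikit-learn's
CART as an independent implementation.

Incremental training uses ten equal folds of the shuffled data. The last
fold is the test set and never enters training or validation. Run t trains
on the accumulated folds 1..t; from run 2 onward, pooled samples
misclassified by the previous run's selected pruned tree ("junk") are
removed first — under label noise these are predominantly boundary or
mislabeled samples, and removing them stabilizes later splits. Each run's
chain is scored on the eight non-test folds outside the newest fold
(validation is held fixed at 80% of the non-test data so run-to-run scores
are comparable; this means folds seen in earlier pools re-enter validation,
a deliberate trade-off at these fold sizes). Among accuracy ties the
simplest subtree wins. The best pruned tree across the nine runs is
returned. A non-cumulative mode (each run trains on its newest fold only)
and `junk_rule="off"` give the ablations. If junk removal would empty the
pool entirely, it is skipped for that run.

## GRU branch

Standard GRU gating (update gate z, reset gate r, candidate state from the
reset-masked previous state), which keeps every hidden component inside
[−1, 1] whenever the initial state is. The input layer standardizes the
beat globally (training-set mean/SD, stored with the parameters) and frames
it into 25 steps of 10 samples; framing shortens the backpropagation path
from 250 to 25 steps, without which credit assignment across a whole beat
is impractically slow at this scale. The head is one tanh fully connected
layer (default 32 units) followed by the softmax class projection.

Defaults: hidden size 64, batch size 128, 30 epochs, Adam at 1e-3,
small-uniform weight init (±0.08, biases zero), L2 coefficient λ = 0.01 on
weight matrices (not biases) with the penalty written (λ/2n)Σw², n the
batch size. An optional auxiliary penalty on the norm of the first
fully connected weight matrix exists (`aux_penalty_coeff`, default 0).
All gradients are computed by manual backpropagation through time in
float64 and are verified against central finite differences to better than
1e-5 relative error in the test suite. Training is exactly reproducible
from the seed under single-threaded BLAS.

## Fusion

Per beat, the CNN input is [h_T ; class logits], the logits recomputed from
h_T through the L2-regularized head — length hidden+4 (68 by default). The
CNN is Conv1D (8 width-3 kernels, SAME, ReLU) → MaxPool1D (width 2, stride
2, SAME: 68 → 34) → global average pooling → dropout (0.2, identity at
inference) → dense → 2-way softmax, so W1 + W2 = 1 and both weights are
strictly inside (0, 1). The fused output is softmax(W1·p_GRU + W2·D_tree).
Training is two-stage: both branches are frozen, then the CNN is fit by
cross-entropy on the fused outputs over the validation split (Adam, 60
epochs). Because the branch outputs enter the loss linearly before the
final softmax, the gradient through the mixing weights is exact and cheap.

When one branch is systematically more reliable, the learned weights shift
toward it; on data where the GRU is near-perfect the mean W2 collapses
toward 0, and in a constructed scenario where the tree branch is strictly
more accurate the mean W2 exceeds 0.5 (both are test-asserted).

## Synthetic data

Beats are sums of five Gaussian bumps (P, Q, R, S, T) on the 250-sample
window with the R apex at index 108. Class rules: N canonical; S with the P
bump attenuated to near zero and a 30%-shortened preceding RR interval; V
with QRS bump widths ≥ 2× normal, inverted T and absent P; F the
element-wise mean of the N and V templates. Strips add RR jitter (5% SD
around 72 bpm), a per-beat global amplitude jitter (3% SD), 0.25 Hz
baseline wander, white Gaussian noise (settable directly or via a target
SNR measured against the clean strip), and an optional powerline tone. The
default class mix (0.7, 0.1, 0.15, 0.05) mirrors the strong class imbalance
of ambulatory recordings. Everything is a pure function of the seed.

What this emulates: distinct, class-dependent morphology; annotated R
positions; realistic rates, imbalance, and additive noise. What it does
not: within-class morphological diversity across patients, non-Gaussian
artifacts (electrode motion, muscle noise), rhythm context, or lead
placement effects. Passing the synthetic benchmark therefore demonstrates
the *correctness* of the pipeline and the *behavior* of its components, not
clinical-grade performance; headline numbers on real archives require the
real recordings.

## Problem sizes and tolerances

The test suite runs the full stack at desk scale: the end-to-end benchmark
uses 2,000 beats (noise-free and at 10 dB SNR) and requires tree and GRU
held-out accuracy ≥ 99% on the separable noise-free set and fused accuracy
within 0.5 percentage points of the better single branch in both settings;
the detector benchmark uses 500 beats at 10 dB SNR with ±50 ms matching
tolerance and requires sensitivity and positive predictivity ≥ 99%; the
experiment suite in tests runs at 400–1,500 beats. Numerical tolerances:
gradient checks at 1e-5 relative, closed-form identities at 1e-9 or
tighter, brute-force oracle agreement at 1e-10 on impurity decreases.

## Known limitations

* The WFDB reader supports single-file format-212 records with MIT-format
  annotations — enough for the standard arrhythmia archives and our own
  fixtures, not the full format zoo.
* Only the first lead is used; no multi-lead fusion.
* Records must be at 360 Hz for segmentation; resample beforehand otherwise.
* The GRU trainer is plain NumPy: fine for 10³–10⁴ beats, not for
  10⁵-beat archives on a deadline.
* Class imbalance is handled by nothing beyond the data itself (no
  resampling or class weighting).
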