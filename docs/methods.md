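# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind the package, and what the synthetic benchmark does and does
not demonstrate.

## The identification problem

The target quantity is the knee's *interactive torque*: a proportional
feedback signal that tracks joint-torque trends for exoskeleton control, not
a direct physiological torque measurement. The identification strategy is
discrete: torque–EMG relationships are learned at fixed postures (20°–130°
in 10° steps, one model per 10° bin) and the bin-wise predictions are fused
into a continuous signal afterwards. This trades angular resolution for
robustness to load and movement-speed variation: each bin's model only ever
sees data from one posture, so it cannot confound posture with effort.

## Preprocessing

- **Band-pass.** 4th-order Butterworth, 10–500 Hz half-power edges. The
  sEMG band is conventionally taken as 10–500 Hz; everything below is DC
  offset, sweat/electrode drift (0.2–0.5 Hz) and motion artifact, everything
  above is instrumentation noise. Applied zero-phase (forward–backward) in
  offline mode; a causal single-pass mode exists for streaming, where the
  half-power attenuation and group delay then apply once.
- **Notch bank.** Second-order IIR notches at 50 Hz and harmonics up to
  450 Hz at fs = 2 kHz (9 sections), quality factor Q = 30. Q trades hum
  rejection against collateral removal of genuine EMG power in a ±0.8 Hz
  band per section; 30 is a common compromise. Harmonics at or above
  Nyquist are skipped with a warning.
- **Hampel identifier.** Stepping (non-overlapping) windows of 750 samples;
  within each window, samples deviating from the window *median* by more
  than k = 3 sample standard deviations are flagged. Flagged samples are
  *replaced by the window median* rather than deleted: deletion would
  desynchronize the EMG from the angle/torque series that downstream
  windowing relies on. The mask is reported alongside. A MAD-based spread
  estimate is available behind a flag; the default follows the
  median-center/ordinary-std formulation.
- **Normalization.** Per-channel min–max onto [−1, 1], per recording; the
  affine parameters are retained so the identical map can be applied to
  streamed continuations. Normalization is the last stage, so the stored
  parameters refer to cleaned signals.

Known limitation: on a perfectly clean input the chain is only an
*approximate* fixed point. The notch bank removes a sliver of real in-band
power, and in windows that straddle a burst onset the Hampel rule flags
legitimate extremes of the high-amplitude half (the pooled window std
underestimates its spread), denting burst-peak windowed RMS by a few
percent (measured worst-window deviation ≈ 7%). This is intrinsic to
stepping-window robust cleaning of non-stationary signals.

## Features and screening

Windows are specified in milliseconds so the same configuration serves both
sampling rates encountered in practice: `acq2000` (200 ms / 50 ms ⇒ 400/100
samples at 2 kHz, 75% overlap) and `train1000` (200 ms / 100 ms ⇒ 200/100
samples at 1 kHz, 50% overlap). The trailing remainder shorter than one
window is discarded.

Per window and muscle: RMS, VAR (N−1 divisor), ZC, WL, MAV. The
zero-crossing count uses a dead-band ε = 0.01 (in normalized units): both
flanking samples must exceed ε in magnitude for a strict sign change to
count, otherwise sensor noise around zero dominates the statistic. The
window's angle label is the angle at the window's center sample; the torque
target is the window mean of torque (robust to sensor jitter; a
center-sample mode exists).

Screening correlates every (muscle, feature) column with torque, scores
features by mean |r| across muscles, and drops the lowest-scoring feature
(drop count 1 by default). A constant feature column (e.g. ZC on signals
that never cross zero) scores 0 rather than erroring. On real recordings ZC
is typically the weakest feature; on this package's synthetic data the
dead-banded ZC acts as an amplitude detector (the carrier is
amplitude-modulated noise) and the data-driven decision usually drops VAR
instead — the decision is recorded in the screening report either way.
Muscles are then ranked by mean |r| over the retained features and the
final channel set keeps the top two extensors and top flexor by default;
the set is configuration, not hard-coded.

## PCA

PCA is fitted independently per muscle on its retained-feature block
(centering, covariance with M−1 divisor, symmetric eigen-decomposition,
eigenvalues descending). Two components per muscle are kept by default —
on both real and synthetic feature sets the first two components carry
≈ 99% of the variance — and a cumulative-variance rule (smallest m reaching
a threshold) is available. Eigenvector signs are fixed by making each
vector's largest-magnitude entry positive, so serialized models are
reproducible. Three muscles × two components + the knee angle give the
1×7 regression input.

## Per-bin networks

Topology n_in–m–1 with tanh hidden units (inputs live in [−1, 1]) and a
linear output. Candidate hidden widths follow m ≤ √(n_in + n_out) + α,
α ∈ 0..10 (for 7 inputs: 3..12); width selection trains one model per
candidate and takes the validation-RMSE argmin (ties to the smaller width).
The default width is 10, a choice that can also be supplied directly.

Training: full-batch gradient descent with classical momentum 0.9 on
MSE + λ‖W‖² (λ = 10⁻⁴), initial learning rate 0.1 halved after 15
plateau epochs (floor 10⁻⁵), early stopping after 50 epochs without
validation improvement, 1000-epoch cap, best weights restored. Plain
full-batch descent without momentum stalls on plateaus of the tanh network
often enough to make small-sample recovery erratic; momentum is the minimal
classical remedy. The validation split is the *chronologically last* 20% of
each bin's windows — windows overlap in time, so a random split would leak
train information into validation. Targets are standardized internally;
predictions are de-standardized and clamped to ±30 N·m (clamping applies at
prediction only, never to training labels). Each bin trains with seed =
base seed + bin index; everything needed for bit-identical inference (bin
spec, weights, PCA models, input scaler, seeds) serializes to one JSON
document.

Input scaling for the networks is a shared per-column min–max map fitted on
the pooled training inputs of all bins; per-recording EMG normalization
happens earlier, in preprocessing.

At prediction time a window routes to the bin whose center is nearest its
angle (ties to the lower center); angles outside the binned range clamp to
the edge bin with a warning, and untrained bins fall back to the nearest
trained neighbour.

## Fusion

The bin-jumping prediction stream is smoothed by a scalar random-walk
Kalman filter — state x = torque, x_{k+1} = x_k + w with w ~ N(0, Q),
measurement z = x + v with v ~ N(0, R); initialized at the first sample
with variance R — followed by a zero-phase 4th-order Butterworth low-pass
at 5 Hz on the prediction-rate stream (20 Hz at the default 50 ms window
shift). Defaults Q = 0.01, R = 1 favour heavy smoothing of bin-switch
artifacts; the steady-state gain has the closed form K = M/(M+R) with
M = (Q + √(Q² + 4QR))/2, which the tests use as an oracle. A
smoothing-heavy filter necessarily lags fast transients (≈ (1−K)/K
prediction steps causally); applications tracking faster torque dynamics
should raise Q/R, as the tracking test demonstrates.

## Synthetic data generator

The generator emulates the discrete acquisition protocol so the pipeline is
testable end to end:

- **EMG model.** Amplitude-modulated band-limited (10–500 Hz) Gaussian
  noise — the standard phenomenological sEMG model. Each channel's
  modulation follows the extension or flexion effort envelope according to
  its role, with per-channel gain variation so muscle ranking is
  non-trivial. It does *not* model motor-unit physiology, spectral
  compression with fatigue, or electrode crosstalk.
- **Artifacts.** DC offset 1.45 V, baseline drift (random-frequency
  0.2–0.5 Hz sine, 0.4 V), 50 Hz hum with 3 harmonics (0.15 V at the
  fundamental), broadband white noise at 10 dB SNR, and impulsive outliers
  (Poisson, 10 s⁻¹, ±25 clean-signal standard deviations ≈ 0.5% of
  samples). The artifact levels are chosen so that preprocessing matters:
  at these defaults the full pipeline passes the recovery bar (below) while
  the identical pipeline with preprocessing disabled fails it — amplitude
  features (VAR, WL) are intrinsically robust to DC, drift and stationary
  hum, so impulsive artifacts are the component that genuinely requires
  cleaning.
- **Torque.** g(angle)·(ext − flex effort)·30 N·m plus N(0, 0.5²)
  measurement noise, clipped to ±30; g is a raised cosine over the joint's
  20°–160° span with floor 0.35 (mid-range torque capacity is highest).
  Extension is positive, flexion negative.
- **Protocol.** Per angle and session, a 12 s trial of six interleaved
  extension/flexion efforts of varying amplitude, the nominal fixation
  angle wandering by at most ±5° (the fixation device's play); 12 angles ×
  2 sessions = 24 trials plus one continuous squat trial (40°–130° sweep)
  for bin routing and fusion. Per-trial seeds derive from the base seed
  and are recorded in the manifest.

## What the benchmark shows — and does not

Training on session 0 and evaluating on session 1 (different noise and
effort realizations) at the default conditions yields held-out per-bin mean
r ≈ 0.98 and R² ≈ 0.88–0.94 across seeds, comfortably above the
pipeline's acceptance bar (mean r ≥ 0.90, R² ≥ 0.80). This demonstrates
that the pipeline recovers a known ground-truth mapping through realistic
artifact levels; it does **not** certify accuracy on human recordings,
where the EMG–torque relationship is nonstationary, subject-specific and
contaminated by crosstalk the generator omits. The per-bin report format
(RMSE/R²/r per angle plus unweighted mean) mirrors how such results are
conventionally tabulated.

## Numerical and degenerate-input choices

- Sample variance and covariance use N−1 divisors throughout.
- Constant channels cannot be min–max normalized and raise an error naming
  the channel; constant *feature columns* in screening score r = 0.
- Zero-variance columns are legal in PCA (zero eigenvalue); an all-zero
  block is an error.
- A series shorter than one analysis window is an error stating the
  required minimum length; a Hampel window longer than the series collapses
  to a single window.
- Scaler columns with zero range map to a finite constant rather than
  dividing by zero.
- All reported determinism is bit-level: identical config hash + seed
  reproduce identical model JSON and report CSV bytes.
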