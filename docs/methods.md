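# Methods

## The analysis in one paragraph

Walking destabilized by a cognitive dual task or mechanical perturbation
changes the cortical rhythms that accompany gait: sensorimotor beta power
falls and frontal-midline theta power rises relative to stable walking.
The pipeline operationalizes this as a classification problem at the gait
cycle level: EEG is filtered and ICA-cleaned, cut into
heel-strike-to-heel-strike cycles, summarized by 29 per-channel
biomarkers (or kept as a raw 100-sample cycle tensor for the sequence
models), reduced to a distinctive low-redundancy feature subset, and fed
to five classifiers evaluated with stratified 5-fold cross-validation
under three labelings (four-class, three-class, stable/unstable).

## Synthetic data generator

Real recordings of this protocol are not redistributable, so the package
ships a generator that emulates the statistical structure the analysis
depends on; every downstream stage is tested against its ground truth.

* **EEG.** Per channel: 1/f-power background (unit-RMS shaped white
  noise, spectral slope −1, scaled to 10 µV RMS) plus band-limited
  Gaussian oscillations assigned by montage region — alpha (8–12 Hz,
  posterior, 20 µV RMS), beta (12–30 Hz, sensorimotor, 20 µV RMS), theta
  (4–7 Hz, frontal-midline, 15 µV RMS). Oscillation amplitudes are
  modulated by gait phase (sinusoid at stride frequency, depth 0.2),
  which gives segmentation something real to preserve. Amplitudes were
  chosen once so that the planted beta effect dominates the beta band on
  sensorimotor channels (background dilutes the power ratio by ≈ 0.015),
  and are larger than typical scalp rhythms; the generator prioritizes
  recoverability of the planted effect over amplitude realism.
* **Condition effects.** STROOP and MLP (unstable) multiply beta power by
  0.7 and theta power by 1.3; NW and COM (stable) are baseline. Stride
  variability: CV 0.03 stable, 0.07 unstable, around a 1.10 s mean.
* **Kinematics.** Heel height is a smooth swing arc plus a sharp
  time-symmetric Gaussian dip (σ = 20 ms, 6 mm) centered exactly on each
  heel strike — the heel decelerates abruptly at contact, and the dip
  makes the minimum well-conditioned for detection. Vertical GRF is a
  double-peaked stance curve (0.75 sin πs + 0.25 sin 3πs over the stance
  fraction 0.6, peak ≈ 1.1 body weight) that rises within a few
  milliseconds of each event, plus 2 N sensor noise.
* **Artifacts (off by default, injectable).** Blinks: Poisson events,
  300 ms sin² transients, frontal-dominant fixed topography (rank-1 —
  separable by ICA); line noise: common-phase 60 Hz sinusoid on all
  channels; EMG: 0.2–0.5 s bursts of >30 Hz noise with a fixed left/right
  temporal topography. Ground-truth stamps are kept in metadata.
* **What it does not emulate:** volume conduction and channel
  correlations, non-stationary background, subject-specific spectra,
  movement artifacts locked to gait phase, electrode drift. Passing
  end-to-end tests therefore demonstrates that the pipeline recovers a
  planted spectral contrast through segmentation, feature extraction,
  selection and classification — not that real EEG of this protocol
  would classify at the same accuracy.

## Preprocessing

Filtering: 4th-order Butterworth sections, band-pass 1–70 Hz plus
band-stop 55–65 Hz, applied forward–backward (zero phase) so gait-event
timing is preserved. ICA: scikit-learn FastICA (unit-variance whitening,
fixed seed, rank check with component reduction). Component scoring is a
rule-based surrogate for trained component classifiers: evidence scores —
eye = sub-4 Hz power fraction × frontal topography share; line_noise =
55–65 Hz power concentration; muscle = >30 Hz power fraction × high-band
spectral flatness; channel_noise = single-channel topography dominance;
brain = 1 − (sum of the others) — mapped through a softmax (sharpness 9)
to probabilities over six labels. Components whose top non-brain
probability exceeds 0.90 are zeroed before back-projection, so channel
count and length are always preserved. No re-referencing is applied
before ICA; EEG and kinematics are assumed to share t = 0.

## Segmentation

Heel strikes from the marker: 6 Hz zero-phase low-pass, local minima with
prominence ≥ 0.25 of range and ≥ 0.4 s separation, refined to sub-sample
precision by a least-squares parabola over ±40 ms (the mocap grid is
10 ms, coarser than the ±10 ms accuracy target). From the GRF: upward
20 N crossings preceded by ≥ 50 ms below threshold, with the crossing
time linearly interpolated. Marker events confirmed by a force event
within 50 ms are kept (marker timing is primary). Cycles are the
half-open spans between consecutive right-side events; durations outside
0.4–2.5 s are discarded and counted. Each channel is linearly
interpolated onto 100 equally spaced points of the cycle (endpoint
excluded, so a stride-periodic signal yields identical cycles); the raw
native-rate slice is kept for the wavelet and Hjorth features.

## Features

Per channel and cycle, 29 features (names `<channel>__<feature>`):

* Time domain, on the normalized 100-sample trace: mean absolute
  deviation about the mean, RMS, max, min, mean, population variance
  (divisor n throughout), skewness m₃/m₂^1.5, kurtosis m₄/m₂²
  (Gaussian → 3), and average amplitude change Σ|xᵢ₊₁ − xᵢ|/(n−1).
* Hjorth activity/mobility/complexity on the alpha- and beta-band
  zero-phase-filtered raw slice; derivatives are unscaled first
  differences.
* Entropies of the normalized trace: Shannon over a 16-bin histogram
  (natural log, 0·log 0 := 0), log-energy Σ log xᵢ² (zeros contribute 0),
  threshold #{|xᵢ| > ε}, SURE n − #{|xᵢ| ≤ ε} + Σ min(xᵢ², ε²), and norm
  Σ|xᵢ|^p, with ε = 0.2·SD(x) and p = 1.5 (both configurable).
* Wavelets: Daubechies-2, 8 levels, on the raw slice (8 levels need
  ≥ 768 samples — infeasible on the 100-sample trace, which is why the
  raw slice carries them). The signal is zero-padded to a multiple of 2⁸
  and decomposed in periodization mode, keeping the transform exactly
  orthogonal, so Σ detail energies + approximation energy = Σ x² to
  machine precision for any length; symmetric padding was rejected
  because it breaks this identity. Features: detail energies d1–d8 and
  their population SD.

Degenerate inputs (zero variance) report 0 for the affected moment-based
features with a warning rather than NaN.

## Feature selection

Two classes: score = |z| of the two-sample Mann–Whitney statistic,
U = #{xᵢ > yⱼ} + ½·ties, z = (U − n₁n₂/2)/σ_U with the tie-corrected
σ_U² = n₁n₂/12·[(n+1) − Σ(t³−t)/(n(n−1))]. More classes: max over
one-vs-rest |z| (keeps the stated statistic; favors any-class
discriminability). Greedy selection: take the top-ranked feature, then
repeatedly the highest-ranked candidate whose mean |Pearson r| with the
already-selected set is ≤ 0.8, until k = 40 (both configurable). Ranking
ties break by column order, making selection deterministic. Selection is
performed once per run by default; a per-fold mode exists because
selection outside the folds leaks label information into the test folds
(both modes are exposed; the default mirrors the selection-then-CV
ordering of the pipeline).

## Classifiers

Feature-based (on the selected, train-fold-standardized features where
the model needs it): SVM with RBF kernel (C = 1, γ = 'scale'), random
forest (500 trees, √d features per split), gradient boosting (xgboost,
300 rounds, depth 4, η = 0.1). Sequence models consume the per-channel
standardized cycle tensors (channels × 100):

* **Stacked LSTM:** 2 × LSTM(64), dropout 0.3 between layers, softmax
  head on the last timestep.
* **ChronoNet:** three inception-style blocks, each concatenating three
  stride-2 1-D convolutions with kernel lengths 2, 4, 8 (32 filters
  each → 96 channels, temporal lengths 100 → 50 → 25 → 13), feeding four
  GRU(32) layers whose inputs are the concatenation of all preceding GRU
  outputs (widths 96, 32, 64, 96); the head applies temporal mean
  pooling over the last GRU sequence before the linear/softmax layer —
  a readout better conditioned for power-like discriminants than the
  final timestep.

Both are trained by the package's own NumPy reverse-mode autodiff
(gradient-checked against finite differences): Adam (LSTM 1e-3,
ChronoNet 2e-3), batch 64, cross-entropy, gradient-norm clipping at 5,
early stopping on a 10 % validation split with best-state restoration,
single precision. Two training-dynamics choices matter and are
deliberate: (i) random circular time-shifts augment every training batch,
because without them the networks memorize the phase-aligned waveforms
of individual cycles instead of learning the shift-invariant band-power
statistic that distinguishes the classes; (ii) GRU update-gate biases are
initialized to +2 so each unit initially tracks its input and gradients
flow through the stacked recurrence. Training restarts with a reseeded
initialization (at most twice) when final training accuracy stays within
0.08 of chance — the non-convex optimization occasionally fails to leave
the chance plateau from an unlucky draw; the criterion uses training
accuracy only.

## Evaluation

Stratified 5-fold CV at the cycle level (the protocol the study design
implies); a subject-wise grouped mode is available because cycle-level
folds let cycles from the same trial appear in both train and test,
which inflates accuracy on real data. Metrics: accuracy, macro
precision/recall/F-score, multiclass Matthews correlation (covariance
form, which reduces exactly to the classical binary MCC), and macro
one-vs-rest ROC AUC, reported under both "ROC area" and "AUC" (one
quantity, two conventional names). Fold averages are weighted by fold
size, so reported accuracy equals trace(confusion)/total exactly.
Confusion matrices are pooled over folds; ROC curves come from the pooled
out-of-fold scores.

## Problem sizes

Default end-to-end scale: 4 subjects × 4 conditions × 120 s at 1000 Hz
EEG / 100 Hz mocap (≈ 1700 cycles), ChronoNet trained 20 epochs
(two-class) or 32 epochs (four-class; its chance plateau is longer). The
demo uses 2 subjects × 60 s × 32 channels with artifacts and ICA on.
With identical spectra for NW vs COM and STROOP vs MLP, four-class
accuracy is structurally capped near (two-class accuracy)/2 + 0.25·
(1 − two-class accuracy) ≈ 0.5; values above 0.40 indicate the
stable/unstable contrast is carried through the full pipeline.

## Known limitations

* The ICA scorer is interpretable but hand-calibrated on the generator's
  artifact families; real muscle/channel artifacts are more diverse.
* Cycle-level CV overstates accuracy whenever trials contribute cycles to
  both train and test; use `group_by_subject` for leakage-free estimates.
* The NumPy sequence models are CPU-sized (tens of seconds per fold at
  the default scale); they are faithful architectures, not a performance
  claim.
* Entropies are computed on the normalized samples (not on wavelet
  coefficients); the choice is configurable.
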