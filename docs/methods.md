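# Methods

## Study design emulated by the generator

The synthetic protocol follows a four-session, six-task battery:
sessions 1–3 each contain four of the six tasks and the final session
contains all six, so every subject sees each task exactly three times
(18 task-sessions). The omitted early session rotates deterministically
with subject index, which bounds the per-task session imbalance across
any cohort at one; only within-session task order is randomised
(seeded). Per task-session, blocks alternate easy/hard (3+3 for working
memory, risk assessment, shifting attention and inhibitory control;
2+2 for situation awareness), except vigilance, which is one continuous
5-minute run split into eight 37.5 s segments, the first four easy and
the last four hard. Default block length is 40 s (30 s where the task
itself is 30 s), with a 10 s inter-block gap and a 30 s pre-task rest
that serves as the optical baseline. These defaults put a task-session
at roughly 5–6 minutes.

## Ground truth and injected effects

Each block carries an explicit parameter record: hemodynamic response
amplitude (µM), per-band EEG power scales, mean RR interval and LF/HF
ratio, saccade rate and mean amplitude, pupil diameter, reaction-time
mean and accuracy probability. Difficulty (condition) raises the
hemodynamic amplitude (+40%), theta power (+30%), pupil diameter
(+0.3 mm), reaction time (+15%) and shortens RR (−40 ms), and lowers
accuracy (−10 points) and alpha power (−15%); repetition (session)
shrinks the hemodynamic response and reaction time and raises alpha —
the usual workload and learning signatures. A per-subject lognormal
gain (σ = 0.10) and offsets on RR and pupil stand in for stable
inter-individual differences, which is what makes the random-intercept
model appropriate.

## Forward models

- **fNIRS**: the canonical double-gamma impulse response (peak 6 s,
  undershoot 16 s, 1:6 undershoot ratio) is convolved with each block's
  boxcar and peak-normalised so the block maximum equals the injected
  amplitude; HbR = −⅓·HbO. Concentrations map to two-wavelength optical
  density through tabulated extinction coefficients
  (ε(730) = [0.446, 1.1022], ε(850) = [1.058, 0.6917] mM⁻¹cm⁻¹,
  HbO/HbR), DPF 6.0 and 2.5 cm separation, and to intensity as
  I = I₀·10^(−ΔOD). Physiological oscillations (0.1 and 0.25 Hz) and
  white noise are added in OD so the inversion is exercised, not
  bypassed. The same constants parameterise the inverse step by
  default; both are config-overridable and cancel in round-trip tests.
- **EEG**: per band, Gaussian noise band-limited by a zero-phase
  order-4 Butterworth, scaled blockwise by the square root of the
  injected power scale (default SDs 4/3/5/2.5/1.5 µV for δ/θ/α/β/γ),
  plus a 1/f background (1 µV RMS), a 20 µV 60 Hz line tone, and
  blink templates time-locked to the ocular simulator's blinks.
- **Cardiac**: one RR series drives both channels — block-wise mean RR
  modulated by 0.1 Hz and 0.25 Hz sinusoids whose variances split
  according to the injected LF/HF ratio (total modulation SD 30 ms)
  plus 3 ms jitter. ECG places Q/R/S/T Gaussian bumps at beat times;
  PPG places an asymmetric (fast-rise, slow-fall) pulse 250 ms later.
- **Ocular**: fixation–saccade alternation with exponential
  inter-saccade intervals; saccade kinematics follow the main sequence
  V_peak = V_max·(1 − e^(−A/A₀)) with V_max = 500 °/s, A₀ = 8°, and a
  raised-cosine position profile (so duration = πA/2V_peak). EOG is the
  gaze trace scaled by 10 µV/° plus 2 µV noise; the same calibration
  constant is the detector default, closing the units loop. Pupil
  carries the injected block means plus slow drift; blinks are NaN
  dropouts in pupil and 150 µV spikes in vertical EOG.

What the generator does **not** emulate: realistic ECG/EEG morphology
and topography, non-stationary artifact regimes, smooth pursuit,
head-motion optics, or correlated cross-modality noise. Passing
recovery tests therefore demonstrates the correctness of the
processing chains and the statistical layer under the stated model,
not robustness to every failure mode of real recordings.

## Processing choices

- IIR filters (notch, band-pass) are applied forward–backward
  (zero-phase) so block-locked features are not delayed; "order" is the
  design order of the prototype. The fNIRS FIR is single-pass with its
  linear-phase group delay (order/2 samples) removed and constant edge
  padding.
- Motion rejection masks samples whose sliding-window (4 s) SD exceeds
  3× the running median window SD, or that sit outside saturation
  limits; masked samples are excluded from every block statistic.
- The optical baseline is the pre-task rest by default; a per-block
  local baseline is available (`baseline_mode="block"`).
- The saccade detector thresholds acceleration at k = 3.4 × a robust
  trailing noise scale (2 s rolling median of |acceleration|, scaled by
  1.4826). A robust scale is essential: saccadic accelerations
  themselves would otherwise inflate a plain SD threshold and suppress
  recall. The speed trace is Savitzky–Golay smoothed (20 ms) before
  differentiation for the same reason. Events are
  acceleration/deceleration peak pairs of opposite sign within 100 ms,
  merged under 80 ms.
- Beat correction replaces manual editing with deterministic rules:
  intervals under 70% of the running median (double detections) are
  deleted; remaining intervals deviating more than 30% from the median
  or outside 250–3000 ms are flagged.
- Cardiac spectral measures use a cubic-spline tachogram at 4 Hz,
  detrending and Welch PSD; relative LF/HF powers are normalised to
  LF+HF (normalised units), so they sum to one by construction. Spans
  under 120 s carry a `reliable: False` flag because the LF band cannot
  be resolved; block-level values on short blocks are emitted but
  flagged. Cardiac features default to per-block computation.
- Eye-tracking emits the seven listed gaze features; the set is
  config-extensible.

## The mixed model

For each measure, `y = Xβ + b_subject + ε` with a subject random
intercept and residual variance free to differ across the six
session×condition cells ("diagonal covariance pattern"; a pooled
homogeneous residual is the non-convergence fallback and an explicit
option). Estimation is REML on the profiled likelihood; the
per-subject block structure of V = τ²11' + diag(σ²) is inverted in
closed form (rank-one Woodbury), and the optimiser works on log
variances (L-BFGS-B) with the response standardised internally.

Fixed effects use sum-to-zero coding, so each factor's coefficient
block tests the marginal (type-III) hypothesis. Denominator degrees of
freedom are Satterthwaite: for each 1-df component of a factor's
contrast (eigen-directions of L·Cov(β̂)·L'), df_i = 2f_i²/(∇f_iᵀ W ∇f_i)
with W the inverse observed information of the variance parameters;
multi-df factors combine components via E = Σ df_i/(df_i−2),
df = 2E/(E−q). In the zero-subject-variance, balanced, pooled-residual
limit the F statistics reduce exactly to the two-way fixed-effects
ANOVA (verified against an independent OLS/ANOVA fit), and null
simulations put the type-I rate at ≈0.03–0.05 at α = 0.05. Effect
size is partial η² = F·df₁/(F·df₁+df₂), asserted to 10⁻⁶ on every
emitted row.

Degenerate inputs: zero-variance responses, single-condition or
single-subject tables raise a `SingularFitError`; batch fitting skips
and logs such measures.

## FDR grouping

Benjamini–Hochberg is applied independently within groups defined as
modality × data-type family × factor — e.g. all 16 optodes of
"HbO peak / session" form one group, all 32 electrodes of
"alpha / condition" another. Non-multichannel measures form singleton
groups, where the BH flag reduces to p ≤ α. Under a full null the
expected false-discovery proportion of BH equals α exactly, so null
simulations are judged by statistical consistency with α, not by a
strict inequality on a finite average.

## PCA variance partition

Block×measure observations are pivoted wide, missing values imputed
with column means (degenerate columns standardise to zero and carry no
loading), and features z-scored; the correlation-matrix
eigendecomposition retains components with eigenvalue > 1. A
modality's share is the eigenvalue-weighted sum of squared loadings of
its features over the retained components, normalised to 100%. The
procedure repeats 30 times over seeded bootstrap resamples of the
rows — which is why the mean retained-component count is non-integer —
and means over repeats are reported. Correlation-based extraction
makes the partition invariant to feature scaling; variance-structure
contrasts between modalities express themselves through
within-modality correlation strength.

## Report-row selection

At most five rows per modality; fNIRS/EEG rows must survive the
grouped FDR; rows sort by partial η² descending; every factor with at
least one eligible row contributes at least one.

## Problem sizes

Tests and the acceptance script run single task-sessions (the feature
count is a per-session invariant), 20–23-subject block tables for the
mixed-model calibration (100–300 null replicates, 40–60 power
replicates), 500 null replicates for FDR behaviour, and 30 bootstrap
repeats for the PCA — sizes chosen to keep Monte-Carlo error well
below the tolerances being checked.

## Known limitations

- The ICA variant of ocular artifact removal is contract-level
  (correlation-thresholded FastICA), not a reproduction of any
  specific ICA implementation; regression is the default.
- The simplified subspace cleaner reconstructs high-variance
  directions per fixed window against calibration statistics; it is
  disabled by default.
- Spectral HRV on 30–40 s blocks is reported but statistically weak;
  the reliability flag should gate any serious use.
- The generator's effects are block-constant; trial-level dynamics
  (fatigue within block, RT sequences) are out of scope.
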