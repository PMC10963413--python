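# mwload — multimodal mental-workload assessment

`mwload` implements a complete analysis pipeline for multimodal
neuroergonomic workload studies: six biomedical recording modalities
(fNIRS, EEG, ECG, PPG, EOG, eye-tracking) captured while participants
perform a battery of six cognitive tasks (working memory, vigilance,
risk assessment, shifting attention, situation awareness, inhibitory
control) at two difficulty levels over repeated sessions. It is aimed
at researchers who want a tested, reproducible reference for the
signal-processing and statistical conventions of such studies, with a
synthetic-data generator that makes every stage verifiable against
known ground truth.

## What it computes

**Signal layer** (per modality, per task block):

- **fNIRS** — raw 730/850 nm intensities → Hamming-window FIR low-pass
  (order 20, 0.1 Hz) → sliding-window motion-artifact rejection →
  modified Beer–Lambert inversion,
  `ΔOD_λ = −log10(I_λ / I_baseline)`, `[ΔHbO, ΔHbR] = (E·L)⁻¹ ΔOD`,
  plus Oxy = HbO − HbR and HbT = HbO + HbR; block features mean,
  slope, peak, time-to-peak, sum (16 optodes × 4 chromophores × 5 =
  320 measures).
- **EEG** — order-8 Butterworth notch at 60 Hz, order-7 band-pass
  1–59 Hz, EOG regression / ICA artifact removal, optional
  artifact-subspace cleaning; 2 s moving-window Welch band powers
  (δ, θ, α, β, γ) and ratio indices, including the engagement ratio
  β/(α+θ) (32 channels × 9 = 288 measures).
- **Cardiac** — Pan–Tompkins-style R-peak detection (ECG) and
  prominence-based pulse detection with false-peak correction (PPG);
  heart rate, SDNN, RMSSD, and Welch spectra of the 4 Hz tachogram in
  LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz), absolute, relative and LF/HF
  (8 ECG measures; 10 PPG with pulse width/amplitude).
- **Ocular** — adaptive acceleration-threshold saccade detection on
  calibrated 2-D EOG; dispersion-threshold (I-DT) fixation detection
  and pupil features on gaze data (3 EOG + 7 eye-tracking measures).

**Statistical layer** (per measure): a linear mixed model

```
value ~ session + condition + session:condition + (1 | subject)
```

fitted by REML with a *diagonal* residual covariance whose variance is
heterogeneous across session×condition cells, per-factor F-tests with
Satterthwaite denominator degrees of freedom, partial
η² = F·df₁/(F·df₁ + df₂), grouped Benjamini–Hochberg FDR across
channels, and a repeated (bootstrap, eigenvalue > 1) PCA that
partitions explained variance across modalities.

## Worked example

```python
import numpy as np
from mwload import synthio, pipeline
from mwload.blockstats import WorkloadLMM

# one synthetic subject performing a working-memory task-session
tsd = synthio.simulate_task_session("sub001", "WorkingMemory", 1, seed=11)
table = pipeline.extract_task_session(tsd)
print(table.groupby("modality")["measure_name"].nunique())
# ecg              8
# eeg            288
# eog              3
# eyetracking      7
# fnirs          320
# performance      2
# ppg             10
```

Fitting the mixed model to a 23-subject block table with an injected
difficulty effect:

```python
res = WorkloadLMM.from_feature_table(table23, "eeg.engagement.CPPz").fit()
print(res.summary())
```

```
Workload mixed model: eeg.engagement.CPPz
  n obs: 414   subjects: 23
  residual structure: by_cell
  REML converged: True
  subject variance tau^2: 0.9444
  residual variances: 1.227, 1.066, 0.7416, 1.113, 0.9104, 1.351

  factor              F           df          p   peta2
  session          9.21 2/236.7      0.000141   0.072
  condition       43.85 1/374.1      0.000000   0.105
  interaction      3.73 2/236.7      0.025490   0.031
```

The condition row reads: across 23 subjects × 3 sessions × 2
conditions × 3 blocks (414 observations), the easy/hard manipulation
shifts the engagement index with F(1, 374.1) = 43.85 and partial
η² = 0.105; the fractional denominator df is the Satterthwaite
approximation under the heterogeneous-residual model.

A command-line surface wraps the same pipeline:

```bash
mwload simulate --out data/ --seed 1 --n-subjects 4
mwload extract data/ --out features.csv
mwload analyze features.csv --out results/
```

## Layout

```
src/mwload/
  synthio.py        protocol schedules + six-modality simulators
  fnirs.py eeg.py cardiac.py ocular.py   per-modality chains
  blockstats/       WorkloadLMM, FDR, partial eta^2, ModalityPCA, report rows
  pipeline.py cli.py config.py types.py  orchestration and interchange
docs/methods.md     model and design notes
```
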