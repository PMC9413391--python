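# Methods

`afsync` detects atrial fibrillation and flutter (merged into one AF class)
in 1–12 lead ECG from the stability of atrioventricular (AV)
synchronization, using six summary statistics per lead set and a small
dense neural network. This note documents the models, the numerical
choices, and what the synthetic data does and does not establish.

## Signal model and preprocessing

Records are amplitude series in mV at a common rate of 500 Hz (polyphase
FIR resampling on ingest; polyphase preserves slopes better than linear
interpolation, which matters because every downstream decision is a slope
criterion). Three zero-phase conditioning stages run per lead:

1. **Power-line cancellation** — a narrow notch (Q = 30) at the configured
   mains frequency (default 50 Hz), applied forward–backward. Contract:
   ≥ 20 dB at the mains line, < 5% amplitude change below 40 Hz.
2. **Baseline removal** — order-2 Butterworth high-pass, forward–backward.
   The single-pass corner is pre-warped by the cascade factor 1.2465 so the
   composite −3 dB point sits at 0.64 Hz.
3. **Adaptive EMG suppression** — Savitzky–Golay smoothing (order 2) whose
   window switches per sample among three regimes: 35 samples in quiescent
   segments (≈ 14 Hz cutoff), 19 over P/T waves (≈ 25 Hz), and 5 inside
   QRS complexes (> 100 Hz, < 5% R-amplitude loss). QRS regions are found
   from a 30 ms slope envelope thresholded at half its 99th percentile
   (robust to broadband EMG noise) and dilated by ±60 ms so the
   low-amplitude Q and S flanks stay sharp; P/T regions are non-QRS
   samples whose 80 ms amplitude envelope exceeds its 75th percentile.

All filters are zero-phase, so fiducial latencies shift by < 4 ms (tested).

## Delineation

Three characteristic points per beat:

* **R-wave** — adaptive-threshold detection on the spatial velocity (the
  absolute first derivative summed over leads, smoothed 40 ms). Running
  signal-peak and noise-peak estimates set the acceptance threshold at
  `noise + 0.35 × (signal − noise)` with exponential (0.75/0.25) updates;
  refractory period 200 ms; gaps longer than 1.5× the running RR median
  are re-scanned at half threshold (search-back). Detections are refined
  to the nearby extremum of summed absolute amplitude. R fiducials are
  detected once on reference lead I and shared across leads, because RR
  statistics are global; Q and P are re-delineated per lead.
* **QRS onset (Q)** — scanning backward from R over [R − 120 ms, R], the
  first sample whose surroundings are isoelectric: |x_t − x_{t−τ}| ≤ Thr_Q
  for every lag τ ≤ 20 ms, plus endpoint bounds 4·Thr_Q (20 ms), 3·Thr_Q
  (10 ms twice). Thr_Q starts at 20 µV and grows by 1 µV until some sample
  qualifies, so the scan always terminates. The all-lags form is essential:
  a single endpoint difference passes spuriously wherever a steep wave
  recrosses its level of 20 ms earlier (e.g. on the exit slope of the Q
  trough).
* **P-/f-peak** — within [Q − 300 ms, Q − 40 ms], candidates must show a
  high-slope deflection against a fixed Thr_P = 3 µV:
  |x_t − x_{t−40}| > 4·Thr_P, |x_t − x_{t+40}| > Thr_P,
  |x_t − x_{t−20}| > Thr_P, |x_t − x_{t+20}| > Thr_P/2. These are
  polarity-blind, so inverted P-waves (aVR) are found. Among qualifying
  candidates the largest total deflection |Δ₋₄₀| + |Δ₊₄₀| wins (the choice
  of tie-break is ours). No qualifying candidate means the beat has no
  atrial peak — a legitimate outcome, not an error, and in AF records with
  sub-threshold fibrillatory activity a common one.

Millisecond windows convert to samples by rounding at the record's rate;
indexing is 0-based. A beat closer than 20 ms to the record start is
skipped with a logged reason.

## Features

Per record: RRi-mean and RRi-std (ms, successive R-to-R distances), and
per lead PQi-mean/PQi-std (ms, P-peak to Q-onset time) and
PQa-mean/PQa-std (mV, amplitude at P minus amplitude at Q, signed). Beats
without a detected P contribute nothing to PQ statistics. Standard
deviations use the sample (n−1) denominator. Dimension is 2 + 4·n_leads:
6 / 26 / 50 for single / six-lead / twelve-lead sets, ordered
[RRi_mean, RRi_std, then per lead PQi_mean, PQi_std, PQa_mean, PQa_std].

Records with fewer than three R fiducials are rejected. A lead with zero
detected P-peaks yields NaN features; the classifier imputes them with
training-set means stored in the model file (the formulation needs finite
inputs and the source method does not state a rule — this is our choice,
recorded here). With exactly one valid beat the std is 0 and a warning is
logged.

## Classifier

A shrinking dense network: input → batch normalization (trainable γ, β per
feature) → 1–3 dense+ReLU hidden layers with non-increasing widths, each
followed by dropout (α = 0.3) → one sigmoid output P(x ∈ AF). Admissible
widths per lead set: {4,8,16} (single), {4,8,16,32,64} (six-lead),
{4,8,16,32,64,128} (twelve-lead), giving 19 / 55 / 83 admissible
architectures (all non-increasing sequences of length 1–3).

Training minimizes class-weighted binary cross-entropy,
`−(1/N) Σ [δ·w_AF·log p + (1−δ)·w_nonAF·log(1−p)]`, with weights
proportional to reciprocal class prevalence normalized to sum to 1 (8% AF
→ (0.92, 0.08)); probabilities are clipped at 10⁻⁷. The optimizer is Adam
(lr 0.001, β₁ 0.9, β₂ 0.999); at most 400 epochs with early stopping after
10 epochs without validation-loss improvement; the checkpoint is the
parameter set at minimal validation loss. Implementation choices the
formulation leaves open, fixed here: batch size 256 (stable BN statistics;
batches of one are skipped since batch statistics degenerate), uniform
±0.05 kernel initialization seeded per run, BN inference from running
statistics with momentum 0.99. Grid search trains each architecture five
times with distinct derived seeds and ranks runs by validation balanced
accuracy, ties broken by fewer parameters. Models persist to HDF5
(parameters, feature ordering, imputation means, threshold).

## Operating point and metrics

Se = 100·TP/(TP+FN), Sp = 100·TN/(TN+FP), BAC = (Se+Sp)/2,
F1 = 2TP/(2TP+FN+FP). The decision threshold is chosen on the validation
set at maximal BAC over the candidate set {0, midpoints of sorted distinct
probabilities, 1}; a record is called AF when its probability strictly
exceeds the threshold. Among equally optimal thresholds the smallest is
returned (maximizing sensitivity at the optimum); the tie-break is ours.

## Shapley explanation

The value function marginalizes missing features over a background sample:
f(S) is the mean model output with features in S fixed to the explained
record and the rest drawn from each background row (the choice of value
function is ours; default background is 100 seeded training records).
Exact values enumerate all 2^M coalitions with weights
|S|!(M−|S|−1)!/M! for M ≤ 15; the 50-feature model uses a
permutation-sampling estimator (default 2000 permutations, seeded) that is
unbiased, satisfies efficiency per sampled permutation, and reports
Monte-Carlo standard errors. Global importance is the mean absolute
Shapley value per feature over a dataset; percent-of-max is reported
rounded to integer percent, and the ranking report flags features above
25% of the maximum and aggregates per lead (excluding the global RR pair)
and per feature family.

## Synthetic data

The generator emulates the two rhythm classes at the study's conditions:
sinus rhythm (55–90 bpm, RR CV 0.02–0.06, Gaussian P-waves of 0.10–0.20 mV
with the physiological polarity map — positive in I/II/aVF, negative in
aVR, low-amplitude in aVL/V1 — and a stable PQ interval of 140–180 ms) and
AF (95–150 bpm, RR CV 0.15–0.30, no P-waves, a continuous two-tone 4–9 Hz
fibrillatory oscillation of 0.02–0.10 mV spanning the 3 µV slope-threshold
regime). RR intervals are log-normal with the configured mean and CV,
truncated at 250 ms (positive support and right skew resemble the AF
ventricular response). The QRS is piecewise-linear (onset exactly 40 ms
before the R apex, Q and S troughs, sharp slopes), so ground-truth
fiducials are exact by construction; P and T waves are Gaussian. Chest
leads reuse the limb-lead template with amplitude scaling. Datasets draw
an AF share of round(n × fraction) — 8% by default, matching the study's
class imbalance — with distinct synthetic patient ids and optional mild
baseline drift and EMG noise.

What passing tests on this data do show: the delineation rules recover
exact fiducials under clean and mildly noisy conditions; the features
separate the two generated classes; the full pipeline trains, selects a
threshold, and classifies held-out synthetic records essentially
perfectly. What they do not show: performance on real ECG, where P-wave
morphology varies continuously, artifacts mimic atrial activity, noise is
non-stationary, and the non-AF class contains confounding arrhythmias —
the published full-scale figures (Se ≈ 92%, Sp ≈ 96% for twelve leads)
cannot be reproduced from synthetic data and are not claimed here.

## Problem sizes

The default study used by the reproduction script is 200 records of 20 s
at 500 Hz (8% AF), a 70/20/10 patient-wise split, and the [16, 8]
twelve-lead architecture — large enough for stable statistics at desk
scale while keeping a full run under a minute. Delineation-recovery rates
are measured over five 20 s sinus records (≈ 1,400 lead-beats).

## Known limitations

* The power-line stage is a stationary notch; the dynamically adapting
  subtraction procedure of the original filtering literature is not
  reimplemented, only its attenuation contract.
* The Savitzky–Golay regime-switching rule is a amplitude/slope-envelope
  heuristic meeting the stated cutoffs, not a reimplementation of the
  cited adaptive mechanism.
* Stratified patient-wise splitting assigns multi-record patients by
  majority label (the source does not say how mixed patients were
  handled).
* Absolute Shapley magnitudes depend on the (unstated) background choice;
  only ratios of published global importances are meaningful comparisons.
* The generator's precordial leads are amplitude-scaled limb templates;
  no realistic R-progression, AFL saw-tooth, or pathology other than
  AF-vs-sinus contrast is modelled.
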