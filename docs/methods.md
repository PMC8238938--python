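# Methods

## Problem and labels

The package classifies deliveries as *normal* or *abnormal* from the last 30
minutes of intrapartum cardiotocography. The outcome label is defined on
postnatal measurements, not on the trace: abnormal iff umbilical-artery
pH < 7.20 **or** 1-minute Apgar < 7, both inequalities strict. Records are
usable only if the CTG lasts at least 30 minutes and at most 16 % of FHR
samples are missing; both boundaries are inclusive (exclusion is strictly
"shorter than" / "more than"). Signal loss is counted on the FHR channel
only — FHR is the classified signal; UC validity is surfaced separately in
diagnostics. An FHR sample is invalid if it is NaN, exactly zero (the
CTU-UHB dropout convention) or outside 50–210 bpm.

## Cohort pipeline

Exclusions apply in a fixed order — stillbirth, multiple gestation, preterm
(< 37 weeks, the clinical definition), insufficient data — and each record is
counted at the first stage it fails, so stage counts are disjoint and sum to
the total removed. Records lacking pH or Apgar are routed to the
insufficient-data stage rather than erroring at labeling time. The
emergency-cesarean exclusion applies to the normal branch only. Balanced
datasets take all abnormal cases and a seeded uniform subsample (without
replacement) of eligible normals.

## Synthetic data: what it emulates and what it does not

The simulator targets the *event and statistical structure* a CTG classifier
sees, not cardiovascular physiology (no baroreflex or hypoxia dynamics).

Traces: UC is a resting tone (10 u) plus Gaussian contraction bumps
(period 180 s ± 5 % jitter, width 70 s, amplitude ≈ 50 u). FHR is a constant
baseline drawn U(110, 160) bpm plus band-limited variability (Gaussian noise
smoothed with a 2-s kernel, scaled so the amplitude parameter ≈ twice the
standard deviation; defaults 10 bpm normal, 3 bpm abnormal — reduced
variability is the hypoxia signature) plus raised-cosine episode pulses.
Raised cosines were chosen because they are smooth, compactly supported and
analytically integrable (area = |depth|·duration/2), giving closed-form test
oracles. Decelerations are time-locked to contraction peaks at their
class-specific lag (early |lag| ≤ 5 s, late lag 30–60 s, variable ±20 s,
prolonged ≥ 120 s duration); episode counts are Poisson with per-class rates
(normal: ≈ 5 accelerations, occasional early/variable decelerations;
abnormal: ≈ 3 late + 0.7 prolonged per 30 min, at least one non-reassuring
deceleration enforced). The rates are design choices — no quantitative event
statistics were available to calibrate against — exposed in
`TraceGenParams.event_rates`. Dropout is planted in contiguous runs
(geometric lengths, mean 30 s) hitting the requested fraction exactly to
within one sample. Draws that push FHR below 50 bpm are retried a bounded
number of times.

Registries: stage sizes default to 5406 deliveries → 15 stillbirths, 316
twins, 775 preterm, 619 insufficient → 3681; 298 abnormal (136 planted
quality failures → 162 usable) and 3383 normal (617 emergency cesareans and
812 planted quality failures → 1954 eligible). Outcome pairs are drawn from
the group-conditional Gaussians — pH N(7.31, 0.05) / N(7.25, 0.11), Apgar
round(N(8.31, 0.65)) / round(N(4.30, 1.81)) clipped to 0–10 — and
rejection-sampled until the pH/Apgar rule reproduces the intended label.
Rejection is necessary because the abnormal mean pH (7.25) lies *above* the
7.20 threshold: many abnormal deliveries qualify through Apgar alone. The
truncation this induces on the normal-group pH shifts its mean by < 0.002,
well inside the 3-standard-error acceptance band. A master seed is split
into per-record substreams, so any subset of traces regenerates identically
(the trace store is lazy).

Passing tests on this simulator demonstrates pipeline correctness and the
models' ability to exploit the planted class structure; it does not
demonstrate clinical performance. Real CTGs have drifting baselines,
non-stationary variability, artifacts that mimic decelerations, and weaker,
noisier class separation.

## Conventional chain

Despiking flags samples outside 50–210 bpm or departing from the last
accepted sample by more than 25 bpm per elapsed step ("visually evident
noise" is not computable; these operational thresholds are config constants)
and replaces flagged runs by the mean of the flanking accepted samples.
Smoothing is a centered 15-point moving average with truncated windows at the
edges.

Episode detection: baseline is a 10-minute centered running median, refined
twice by excluding samples deviating > 15 bpm and re-taking the median — a
plain running median collapses when decelerations occupy more than half the
window, which happens in severely abnormal traces. Candidate events are
maximal runs where the magnitude of the analytic signal (Hilbert envelope) of
the deviation exceeds 60 % of the 15-bpm gate; each run may hold several
episodes (a deceleration directly followed by an acceleration shares one
envelope run), so the extremum's episode is carved out and the remainder
re-examined. Onset/offset are estimated from the deviation-weighted second
moment of the pulse support: the moving average adds a known variance
(W² − 1)/12 which is subtracted, and a raised-cosine pulse of duration D has
deviation-weighted variance D²(1/12 − 1/2π²), giving a duration estimate
unbiased by smoothing. An episode is kept if it lasts ≥ 15 s and its depth
estimate — the larger of the observed extremum and the area-equivalent peak
2·area/duration (the moving average attenuates peaks but preserves areas) —
reaches 15 bpm. These gates are the standard clinical acceleration criteria,
applied symmetrically to decelerations. Features are the acceleration count
and the summed deceleration area. The SVM is radial-basis with C = 1 and
inverse-variance kernel width on z-scored features; k-means uses k = 2 with
10 seeded restarts and majority-vote cluster-to-label mapping (ties map to
abnormal).

## CNN

Input is the 2 × 1800 one-hertz window with invalid samples linearly
interpolated beforehand (the network has no mask channel); the classifier
wrapper scales channels by fixed constants (FHR/200, UC/100) for
conditioning. Layer stack: temporal convolution (kernel 30 ≙ 30 s, 4
filters, same padding, no bias) → batch norm → depthwise convolution across
the two signal channels (multiplier 2, no bias) → batch norm → ELU → average
pooling 4 → dropout 0.25 → separable convolution (depthwise kernel 7, then
pointwise to 8 filters, no bias) → batch norm → ELU → average pooling 4 →
dropout → flatten (8 × 112 = 896) → dense to 2 with softmax. A 2-unit
softmax head is mathematically interchangeable with the
sigmoid-"abnormality" reading under categorical cross-entropy at 2 classes.
Temporal sizes follow floor division (1800 → 450 → 112, discarding the
2-sample remainder at the second pooling).

Parameter accounting counts 4 values per batch-norm feature (scale, shift,
moving mean, moving variance); under this convention — and only with
bias-free convolutions — the default configuration closes at exactly 2,130,
verified against model introspection for random configurations. The filter
counts and pooling widths not fixed by the architecture constraints
(4–8 filters, 30-sample kernels) are the unique small solution consistent
with that total and are exposed in `CTGNetConfig`.

Training: Adam (lr 10⁻³, ε 10⁻⁵, β 0.9/0.999), categorical cross-entropy,
batch 16, seeded shuffling and dropout, optional early stopping on
validation loss (patience 20). Batch-norm moving statistics use momentum
0.9. Everything is NumPy; gradients are verified against finite differences
in the test suite. Training is deterministic per seed on one thread.

## LSTM risk index

Two identical predictors (2 stacked LSTM layers × 40 units, forget-gate bias
1) are trained separately on normal-only and abnormal-only traces to predict
the next (FHR, UC) sample from the preceding five samples of both channels,
channels scaled to FHR/200 and UC/100 for stable optimization. The recurrent
output passes through a rectified-linear activation into a linear dense head.
At test time absolute errors are aggregated in consecutive 5-s bins and
summed; since the bins partition the trace, the binned total equals the raw
error sum (kept as an identity check), and
`risk_index = error_normal − error_abnormal` with decision threshold 0 by
default. Training cost is bounded by a seeded subsample of prediction windows
(default 20,000 per model).

## Evaluation protocol

Positive class = abnormal. F1 is the harmonic mean of precision and recall
with 0/0 defined as 0 (logged as degenerate). The ROC sweeps the distinct
observed scores; trapezoidal AUC equals pair counting with half-credit ties
(property-tested exhaustively at small n and against scikit-learn). Tenfold
cross-validation partitions the abnormal cases into ten disjoint test folds,
resamples the normal pool each repetition, and splits 9:1; no record id ever
appears in both train and test (asserted). Model comparison reports the
two-sample Student's t-test (df = nₐ + n_b − 2) and, when the per-seed lists
align, the paired variant (df = n − 1), with degrees of freedom printed —
the two-sample form is the headline number.

## Benchmark problem sizes

The bundled benchmark trains on 162 traces per class (the cohort pipeline's
per-group size) with three training seeds and a stratified 70/30 split per
seed, 40 epochs; this keeps a full run around a minute on one CPU core while
leaving the CNN's test AUC comfortably separated from chance. The LSTM
branch is optional in the benchmark (3 epochs, 8,000-window cap) since its
training cost is dominated by window count, not trace count.

## Known limitations

- The simulator's constant baseline and stationary variability make the
  class structure more separable than clinical data; benchmark AUCs near 1.0
  are a property of the simulation, not a clinical claim.
- The Hilbert-based episode boundary rule is one defensible reading of
  envelope-gated detection; merged adjacent episodes of the same sign are
  returned as a single episode.
- The WFDB reader supports the format-16 integer encoding used by CTU-UHB
  style records only.
- The moment-based boundary estimator assumes a smooth unimodal pulse; on
  strongly asymmetric real decelerations its onset/offset are approximate.
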