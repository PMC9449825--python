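# Methods

## The analysis problem

Given multi-device IMU recordings of a lumbar rehabilitation session,
classify (a) which of 8 exercise-task classes (6 dynamic McKenzie-style
exercises, 1 static lying exercise, 1 pooled ADL class) a 5-second
window belongs to and (b) whether a sitting window shows poor (slouched)
or acceptable posture — and determine which device locations and sensor
channels a deployable wearable actually needs. Because generalization
to *new people* is the clinically relevant claim, every evaluation is
participant-grouped: folds partition participants, never segments, and
a guard raises if any fold assignment splits a participant.

## Generative model (simkit)

No recordings are distributed with this package; a kinematic simulator
stands in for them. It is deliberately *not* a musculoskeletal model —
it generates the statistical structure the analysis depends on, from
physically consistent first principles.

**Conventions.** Earth frame NED (z down); Hamilton scalar-first unit
quaternions mapping earth to sensor coordinates; the accelerometer
reports specific force, reading (0, 0, −9.81) m/s² at rest under
identity orientation; the magnetometer sees a 50 µT field at 60°
inclination; gravity g = 9.81 m/s².

**Orientation.** Each activity fixes a base pose (standing, sitting,
prone, supine) per device location. Dynamic classes superimpose a
quasi-sinusoidal rotation about the plane-appropriate axis — sagittal
→ pitch, frontal → roll, transverse → yaw. Exercise movements use a
one-sided "(1−cos)/2" profile (move to end range and return), except
seated rotation which twists symmetrically; this is what makes left
and right side glides distinguishable in principle (their mean roll
differs in sign) rather than mere phase shifts of each other. The ADL
class is a gait-like mixture: thigh/ankle pitch swing at ~0.9 Hz with
an anti-phase ankle lag, a slower roll sway, and a vertical bounce at
step rate. The quaternion derivative is computed analytically (product
rule over the axis-angle factors), so the gyroscope channel is exact
rather than numerically differentiated; tests verify it against an
independent central-difference oracle (≤ 1e-3 rad/s for the
quasi-sinusoidal classes; the gait mixture gets a looser bound because
the oracle's truncation error grows with movement frequency cubed).

**Channels.** Gyroscope = vector part of 2·q̇⊗q*, resampled to 25 Hz.
Accelerometer = (linear acceleration − gravity) rotated into the
sensor frame; dynamic classes contribute a tangential lever term
(0.25 m effective lever). Magnetometer = earth field (plus ambient
disturbance, below) rotated into the sensor frame. Quaternion channel
= the fused orientation at 50 Hz, with fusion artifacts (below).
Pressure = barometric baseline + per-session bias + white noise at
13 Hz; the default protocol's activities are all floor-level, so
elevation is not modeled and the barometer is an uninformative control
channel by construction.

**Participant random effects** (drawn once per participant):
amplitude_scale ~ LogNormal(0, 0.15), period_scale ~ LogNormal(0, 0.1),
per-location mounting offsets ~ Normal(0, 5°) per axis, phase ~
Uniform(−π, π), noise_scale ~ LogNormal(0, 0.1). The cohort defaults
to 19 participants with a 12:7 male:female ratio.

**Realism mechanisms.** Four artifacts of real multi-IMU sessions are
modeled explicitly because the sensor-selection question hinges on
them; without them every device carries noise-free class-determining
orientation and no device is more necessary than another:

1. *Free-limb placement.* Wrist, ear and shoulder devices draw a
   per-recording orientation offset (SD 25°/15°/12°) — arm and head
   placement is only loosely determined by the activity. Strapped
   lower-body devices do not.
2. *Execution jitter.* A slow multiplicative envelope (5–20% depth,
   0.05–0.12 Hz) modulates movement amplitude: people do not perform
   repetitions identically.
3. *Ambient magnetic disturbance.* A hard-iron-like earth-frame field
   offset (SD 6 µT per axis) is drawn per recording. It corrupts the
   raw magnetometer and — because sensor-fusion heading is
   magnetometer-slaved — appears as a per-recording yaw error in the
   fused quaternion. A slow random-walk drift (0.5°/√s) is added on
   top of the quaternion channel.
4. *Facing direction.* Each recording draws a uniform heading shared
   by all devices. Gravity-referenced channels are unaffected; the
   magnetometer and the north-referenced quaternion see it, which is
   what makes absolute-heading features uninformative across sessions.

**Sensor noise defaults** (consumer-IMU-like): accel 0.3 m/s², gyro
0.05 rad/s, mag 1.5 µT, pressure 5 Pa white noise, plus per-session
biases (0.1 m/s², 0.02 rad/s, 0.5 µT, 20 Pa). `NoiseModel.zero()`
disables every imperfection, restoring exact physics (used by the
invariant tests).

**Posture classes.** Poor sitting applies a +20° lumbar pitch offset
at the lower back (40% of it at the upper back — a slouch is lumbar
flexion, seen only partially higher up); good and forced-good sitting
differ by only 2.5°, far below the 5° between-participant mounting
variability, so they are deliberately not separable across
participants. This motivates the default binary posture task (poor vs
the two merged upright classes); the 3-class variant remains available.

**Determinism.** One top-level seed; every child generator derives
from a SHA-256 hash of (seed, participant, activity, location), so
datasets are bit-reproducible and independent of generation order.

## Feature engineering

23 features per channel per window: mean, median, min, max, SD,
variance, skewness, kurtosis, absolute energy Σx², absolute sum Σ|x|,
RMS, coefficient of variation, mean absolute deviation, IQR, range,
mean and mean-absolute first differences, waveform length Σ|Δx|, zero-
and mean-crossing counts, least-squares slope, mean spectral energy
and dominant-frequency index of the de-meaned one-sided spectrum.
Numerical choices: population (biased) moment estimators, excess
kurtosis; zero-variance windows define skewness/kurtosis as 0;
coefficient of variation is 0 when |mean| ≤ 1e-12; crossings count
strict sign changes only; the slope regresses on the sample index.
Standardization (zero mean, unit variance, constant columns → 0 with
an SD floor of 1e-12) is fitted on each training fold inside
cross-validation, never globally, to avoid test-fold leakage.

## Models

Nine engineered-feature families with explicitly frozen defaults
(pinning the moving target of library defaults): decision tree (Gini),
random forest (100 trees), XGBoost (100 rounds, η 0.3, depth 6,
hist), 5-NN (Euclidean), SGD hinge-loss linear SVM, LDA (SVD), Gaussian
naive Bayes, RBF SVM (C = 1), MLP (one hidden layer of 100, ReLU,
Adam). Hyperparameter names are schema-validated per family. The CNN
operates on raw standardized segments: three same-padded 1-D
convolutions (128/256/128 channels, kernels 8/5/3, ReLU), global
average pooling, L2-normalized embedding, fully connected softmax
head; Adam, categorical cross-entropy, learning rate 0.001, batch 32,
100 epochs, no early stopping. It is implemented directly on numpy
(im2col convolutions with analytic backward passes) so the package
has no deep-learning framework dependency; it is sized for desk-scale
experiments. No class weighting or resampling is applied during
training; class imbalance is handled only at evaluation via the
class-weighted F1.

## Evaluation protocol

Grouped k-fold (default k = 6; k = 10 for final configurations):
distinct participants are shuffled by seed and dealt round-robin to
folds, so fold sizes differ by at most one. The metric is per-class F1
weighted by test support, with 0/0 classes scored 0. Fold mean and SD
(population SD over folds) plus pooled and per-fold confusion matrices
are reported.

Feature importance comes in two flavors. Impurity (Gini) importance is
read from tree-family models (gain scores for the boosted model) and
normalized to sum to 1. Permutation importance is computed on held-out
fold data only: baseline weighted F1 minus the mean score over seeded
permutations of a column, averaged across folds. Because the 2576
engineered features are heavily correlated, per-column permutation
drops vanish (any single column is expendable); the grouped variant
therefore permutes all columns of one device-location × channel block
jointly — the standard joint-permutation remedy for correlated
features — and is what populates the location × channel importance
grid. Defaults are 10 repeats over all folds; the wide full-montage
grids in the acceptance analyses use 5 repeats on 3 folds as a
problem-size choice.

## Search and selection

A trial is one cell of (window width × overlap × model spec × sensor
configuration × task), enumerated deterministically; widths default to
{0.5, 1, 2, 3, 5} s for engineered models, overlaps to {0, 0.2, 0.4,
0.6}. Featurization over the union of requested sensors is cached per
window setting and sensor configurations are taken as column subsets,
so the sensor axis of the search is cheap. Per-trial failures are
recorded without aborting the run; results are cached by configuration
hash. Selection filters trials by deployment constraints (device
budget, location whitelist, garment presets such as the lower-body
"pants" trio, with or without a watch) and ranks by mean F1, then
lower fold SD, then fewer devices, then fewer channels, then
lexicographic key — fully deterministic.

## Problem sizes

The default experiments run at: 19 participants × 11 activities
(dynamic exercises 6 repetitions ≈ 24 s, static holds and postures
40 s, ADL 180 s), giving 1748 five-second segments (1292 exercise,
456 posture); the sensor-recovery study uses 10 independent 8-participant
cohorts with 30-tree forests across a 13-configuration lattice. These
sizes were chosen so a complete analysis runs comfortably on a single
CPU while keeping ≥ 8 participants per fold-side in every split.

## What synthetic results do and do not show

Passing tests demonstrate that the pipeline is correct (windowing
arithmetic, feature definitions, leakage-free grouped CV, importance
aggregation, deterministic selection) and that it *recovers planted
structure*: classifiers separate classes the generator made separable,
the importance grid peaks at the lower-body devices the generator made
most informative, and subset selection returns the lower-body trio.
They do not validate clinical performance: the simulator has no soft-
tissue artifact, no exercise-form errors, no mislabeled bouts, and its
class geometry is cleaner than real movement data, so absolute F1
values on synthetic data sit above what identical models achieve on
real recordings. Trends (window-width gains, device-subset ordering)
are the meaningful quantities, not the absolute scores.
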