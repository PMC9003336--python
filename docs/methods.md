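# Methods

This note documents the models, protocol and numerical choices behind
`intentfuse`: what each stage computes, which parameters matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## Classification problem

Each trial is one execution of a reach/grasp activity by one participant,
recorded by a network of sEMG electrodes (one channel each, 1000 Hz) and
IMUs (orientation quaternion, accelerometer, magnetometer — ten channels,
60 Hz). Activities group into three intent categories, and the category
is the classification target. Only the first 1000 ms after activity
inception are used, so the task is early intent inference rather than
whole-movement recognition.

## Signal conditioning

sEMG channels pass through a causal 4th-order Butterworth band-pass
(10–500 Hz) and are divided by the per-muscle maximal-voluntary-
contraction (MVIC) reference amplitude, putting all muscles on a common
unitless scale. Two conditioning choices deserve note:

* A band edge of 500 Hz equals the Nyquist frequency at 1000 Hz sampling,
  where a digital Butterworth design is undefined; the upper edge is
  clipped to 0.99 × Nyquist with a logged warning.
* Filtering is single-pass causal by default (consistent with real-time
  use); zero-phase forward–backward filtering is available via
  `FilterSpec(zero_phase=True)`. Since both the filter and MVIC scaling
  are linear, the two operations commute.

IMU channels are used raw. No resampling is needed because fusion happens
at decision level — the two modalities never share a feature vector
inside the modular method.

## Features

sEMG signals are segmented into 200 ms windows advanced by 50 ms
(consecutive windows overlap by 150 ms; a 1000 ms trial yields 17
windows). Within each window the standard myoelectric set is computed:
integrated EMG, mean absolute value (MAV), variance about zero
(Σx²/(N−1)), root mean square, waveform length, autoregressive
coefficients to order 4, and the median and mean frequency of the window
periodogram — eleven values per window. The MAV slope (difference of MAV
to the previous window, 0 for the first) is a cross-window quantity; the
default `table1` preset therefore excludes it, and the `full` preset
(twelve values) includes it.

Numerical choices:

* AR coefficients are fit by explicit least squares (covariance method:
  lag-matrix normal equations). This keeps every default feature exactly
  reproducible by a brute-force formula, which the test suite exploits; a
  Burg-recursion estimator (often preferred for very short windows) is
  available via `ar_estimator="burg"`.
* Spectral statistics use a single boxcar periodogram after mean removal;
  the median frequency is the first frequency-grid point at which
  cumulative power reaches half the total.
* IMU sensors contribute the raw ten channel values of the last sample at
  or before the classification horizon (`imu_mode="window_mean"` averages
  instead). Horizon masks tolerate ~1e-12 relative timestamp round-off so
  a sample nominally at the horizon is always included.

## Classifiers

Both methods use stored-exemplar nearest-neighbour classification with
one neighbour and a fractional Minkowski metric, d(x, y) = (Σ|xᵢ−yᵢ|^0.5)²
(the final power is monotone and thus skipped internally). With k = 1 any
neighbour-weighting kernel is inert, so the fractional exponent is the
reading of "distance exponent 0.5" that actually changes behaviour; the
exponent is configurable. Features are not standardised before distance
computation by default. Determinism is guaranteed by canonicalising
training rows (stable sort by row id) and breaking distance ties towards
the lowest canonical index.

Per-sensor (MM) sEMG classifiers label every window; the trial-level
decision is the modal window label, with count ties resolved to the label
of the latest tied window (later windows carry more class information by
construction). The combined classifier (NMM) uses one row per trial: the
concatenation over sensors of all window features (sEMG) and the
horizon sample (IMU). Under dropout the NMM's missing columns are set to
0 and classification proceeds with no special handling — this zero-fill
behaviour is precisely the fragility the dropout experiment measures.

## Bayesian fusion

Sensor s's reliability is a row-stochastic confusion matrix
P_s(predicted j | true i), estimated on the probability-learning set with
additive smoothing (pseudo-count 1 by default): probs = (counts + s) /
(row_total + C·s). Smoothing matters because the probability-learning set
is small (~30–80 trials over 3 classes here); an unsmoothed zero entry
would annihilate the posterior of any class it touches. An all-zero row
with zero smoothing falls back to a uniform row. A sensor's scalar
accuracy is trace(probs)/C — the mean per-class recall (balanced
accuracy), which is what the split-optimisation step maximises.

Fusion multiplies, per class, the prior with each active sensor's
likelihood column and normalises over classes; the two-class case reduces
exactly to the binary odds form with the complement class as the
"event-absent" hypothesis. Log-space accumulation (in sorted sensor order,
making the result exactly permutation-invariant) prevents underflow in
large networks. The default prior is uniform; argmax ties resolve to the
lowest class index; with zero active sensors the posterior is the prior.

## Evaluation protocol

Leave-one-out cross-validation over trials. Per fold, for the MM only,
the 164-trial (at full design) training pool is split into halves with
approximately equal numbers of trials per participant and per activity:
replicate trials within each (participant, activity) stratum are shuffled
and dealt half-and-half, odd strata placing their extra trial in a random
half (imbalance ≤ 1; in degenerate tiny pools one trial is moved so both
halves are non-empty). One half trains the per-sensor models, the other
populates the confusion matrices. The split is re-drawn five times and
the candidate with the highest mean per-sensor balanced accuracy is kept
(ties → lowest repeat index). The NMM needs no split and trains on the
full pool.

Sweeps:

* **Time**: horizons 200..1000 ms in 50 ms steps, all sensors active; the
  trend is Spearman's rank correlation of accuracy against horizon
  (average ranks under ties, equal to the classical 1 − 6Σd²/n(n²−1) form
  when ties are absent).
* **Sensor count**: R = 1..24; per R, random sensor combinations are
  drawn (all distinct combinations when fewer exist than requested — at
  R = 24 the point collapses to a single combination) and both methods
  are evaluated per combination, the MM selecting its per-fold split by
  the active subset's mean accuracy. 95 % intervals are Student-t over
  combination accuracies.
* **Dropout**: both methods trained once with all 24 sensors; for each
  N = 0..23, random dropped sets are drawn. The MM excludes dropped
  sensors from fusion and — deliberately — reuses the confusion matrices
  learned with all sensors present; the NMM zero-fills. Intervals are
  t-intervals over repetition means (each repetition averaging the
  configured number of dropped-set draws). The MM/NMM mean-accuracy ratio
  is reported per N with its range.

Interval construction (t over combinations/repetitions) and tie handling
in Spearman's coefficient are implementation choices documented here
because the protocol itself does not pin them down; identical-valued
samples yield an exactly zero-width interval.

Implementation note: every classifier involved is a 1-NN under one fixed
metric, so all pairwise distance terms are precomputed once per horizon
(per-sensor window-level tables for the MM; per-sensor trial-level block
sums for the NMM, whose distance decomposes additively over feature
blocks, with dropout entering as a per-training-row constant). Every
fold/split/combination evaluation is then pure indexing, which is what
makes the full protocol tractable at desk scale. The test suite verifies
that this fast path agrees exactly with the explicit model-bank + fusion
route.

## Synthetic data

The generator emulates a laboratory session: `TrialDesign` (default
5 participants × 11 activities × 3 trials = 165 trials of 1000 ms, 11
activities mapped onto 3 categories in contiguous blocks) and a default
network of 12 sEMG + 12 IMU sensors whose `informativeness` κ cycles
through {1.0, 0.85, 0.7, 0.55, 0.4, 0.1} — a heterogeneous network
including near-uninformative sensors, as a real multi-environment
deployment would contain.

* **sEMG**: amplitude-modulated band-limited noise. The envelope is a
  baseline plus two logistic ramps; ramp *onsets* are per-sensor (classes
  do not differ in when movement starts) while ramp *amplitudes* are
  category-specific, scaled by κ, so between-class amplitude divergence
  grows smoothly from zero as the ramps engage mid-trial. The carrier
  mixes a low band (10–100 Hz) and a high band (150–450 Hz) with a
  category-specific, κ-scaled, time-ramped mixing fraction, so spectral
  features (median/mean frequency, AR shape) also become informative as
  the trial progresses. The signal is scaled by the sensor's MVIC
  reference and by participant (multiplicative gain, sd 0.18) and trial
  (gain sd 0.12, onset jitter sd 0.05 of trial length) effects.
* **IMU**: a category-specific rotation about a per-category axis whose
  angle follows a minimum-jerk profile (10τ³ − 15τ⁴ + 6τ⁵), scaled by κ.
  The orientation quaternion reports this rotation plus a per-participant
  mounting bias and additive noise (renormalised to unit norm);
  accelerometer and magnetometer report gravity and a fixed ambient field
  seen through the inverse orientation, plus offsets and noise. Because
  every channel's class dependence enters through the rotation, whose
  angle starts at zero, between-class divergence again grows with elapsed
  time.
* All sensor "prototype" geometry (ramp amplitudes, rotation axes, band
  shifts) is fixed independently of the dataset seed, so different seeds
  change noise realisations and participant effects, not task difficulty.
  Every random stream derives from `SeedSequence((seed, domain, indices))`,
  giving exact reproducibility and order-independence.
* Noise scales were chosen so that a fully informative sensor is near
  chance at a 200 ms horizon and clearly but imperfectly separated
  (single-sensor accuracy ~0.7–0.85) at 1000 ms.

`class_separability` is a diagnostic: the ratio of between-class to
within-class scatter of per-trial summary profiles (per-channel mean
rectified amplitude in consecutive 200 ms bins up to the horizon). Later
horizons extend the profile with more discriminative bins, so the
expected score grows with the horizon; because late-trial within-class
noise is largely multiplicative, the curve saturates rather than strictly
increasing, and tests assert monotonicity up to a small estimator
tolerance.

**What the generator does not emulate**: motor-unit action potentials,
soft-tissue artefacts, electrode lift-off, and — importantly — any
*cross-sensor* correlation beyond the shared class label. Sensors are
conditionally independent given the class, which is exactly the
assumption Bayesian fusion makes. Two consequences for interpreting
results on synthetic data: the combined classifier enjoys no
information advantage from cross-sensor feature relationships, so its
no-dropout accuracy ratio to the MM hovers near 1 rather than clearly
above it; and passing tests demonstrate the machinery and its qualitative
behaviour under dropout, not performance on real recordings.

## Problem sizes

The sweep experiments and the acceptance script run on a reduced design —
5 participants × 6 activities × 2 trials (60 trials) with the full
24-sensor network — and desk-scale replication (10 sensor combinations ×
5 repetitions; the CLI's `--full` flag restores 50 × 20). These sizes
were chosen as the smallest at which the sweep statistics are stable
across seeds. Design-count checks (165 trials, 164-trial training pools)
use the full default design.

## Known limitations

* With 60 trials and 24 sensors both methods saturate at accuracy 1.0
  beyond ~550 ms horizons, which compresses the upper end of the time and
  sensor-count curves (rank ties cap the Spearman coefficients below 1).
* The MM's window-vote and the fractional-metric reading of the distance
  specification are documented choices among several defensible ones;
  both are config-switchable.
* Dropout is externally signalled (the fusion layer is told which sensors
  are absent); detecting dropout from the data stream is out of scope.
* No statistical comparison beyond confidence-interval overlap is
  performed between the methods.
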