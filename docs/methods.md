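# Methods

## Scope

The package implements a complete activity-recognition analysis for ten
electrical-line-worker tasks measured by one wrist-worn tri-axial
accelerometer at 32 Hz: synthetic data generation, plain-text I/O,
windowing, three feature domains, two classifier-evaluation protocols,
ANOVA-based model comparison, and interpretation with signal
reconstruction. All stages are deterministic given their seeds.

## Synthetic cohort model

No public recordings of the ten-task protocol exist, so the package ships a
generative stand-in whose statistical structure matches what the analysis
assumes about the real signals:

* **Static postures** (sitting, standing, typing, overhead, electrical
  panel) are dominated by the gravity vector expressed in sensor
  coordinates. Each task has a fixed unit `gravity_dir`; sitting and
  standing differ by ≈ 46°, so their per-axis means separate even though
  both have ≈ 1 g magnitude — the reason per-axis signals are kept instead
  of the acceleration magnitude.
* **Cyclic tasks** (walking, pushing, ladder, plus weaker components in
  typing, overhead, electrical panel, lifting, hoisting) add sums of
  sinusoids. The gait-driven tasks carry their dominant component in the
  1–2.5 Hz band.
* **High-dispersion tasks**: hoisting has the largest per-axis noise sd
  (0.5 g on X — hoisting loads the upper body and induces quiver, with the
  X axis most affected) and frequent Poisson-timed impulses. Impulses are
  one-sample spikes convolved with a 5-sample Hann kernel, producing the
  abrupt transients the wavelet features are designed to catch.
* **Axis dominance**: the electrical-panel task concentrates its static and
  dynamic content on the Z axis (gravity component 0.95, periodic
  amplitudes 0.30 g at 1 Hz and 0.12 g at 2.5 Hz), giving the
  interpretation stage a class with a known axis signature to recover.

**Durations.** Timed tasks run 3 minutes. The protocol specifies the
repetition tasks by count (hoist 10, lift 20, push 10, ladder 20
repetitions), not duration; they are mapped to continuous segments of fixed
per-repetition duration — 9 s for hoist/lift/push, 6 s for ladder — chosen
so every task yields at least 9 windows at 10 s. These per-rep durations
are a modeling choice, not an inference about the original protocol.

**Subject heterogeneity.** Each subject draws an amplitude scale
LogNormal(0, 0.15), a relative frequency jitter U(−0.15, 0.15), and a
rotation of all gravity directions about a random axis with angle
U(0°, 20°). This is enough spread that generalizing to unseen subjects is
genuinely harder than within-subject testing, without collapsing class
separability. `CohortConfig.homogeneous()` zeroes all three, which makes
the two protocols agree — a recovery property the tests assert. All
randomness descends from `master_seed` via `SeedSequence` spawning.

**What the generator does not emulate:** joint kinematics, fatigue drift,
intermittent/mixed task schedules, sensor artifacts (clipping, dropout),
and real between-day variability. Passing tests therefore demonstrate that
the pipeline recovers structure *of the kind assumed*, not field accuracy
on real workers.

## Feature extraction

* **Butterworth filter** (time features only): 4th-order low-pass at
  10 Hz — human movement rarely exceeds 10 Hz. Implemented as a causal SOS
  filter with the state initialized to steady state for the first sample:
  DC gain is exactly 1 and a constant signal passes unchanged; the −3 dB
  point sits at the cutoff.
* **9 statistics**: MAD is the mean absolute deviation about the mean
  (matching its expansion as "mean average deviation"); sd uses the n−1
  denominator; percentiles use linear interpolation.
* **Frequency features** use the raw (unfiltered) signals: magnitudes of
  the FFT coefficients at frequencies strictly below 10 Hz, DC included —
  the single rule that yields 40 bins/axis at 4 s and 100 at 10 s (120/300
  total). Magnitudes (not complex pairs or power) are the standard HAR
  convention and match the printed dimensions.
* **Wavelet features** use db4 with *periodization* boundary handling, so
  band lengths halve exactly and decompose→reconstruct is exact to machine
  precision. Depth is the maximum admissible level
  `floor(log2(n/(filter_len−1)))`: 4 levels at 128 samples, 5 at 320.
  Per band: Shannon entropy of the normalized squared coefficients
  (natural log; 0 for an all-zero band), strict sign-change counts before
  and after mean removal, plus the 9 statistics — 12 descriptors × (L+1)
  bands × 3 axes = 180/216. The entropy and crossing definitions are
  documented choices; the field uses several variants.

## Classification protocols

Grids: k-NN neighbors {1, 4, …, 28} × {euclidean, manhattan} × {uniform,
distance}; SVM C ∈ {0.01, 0.1, 1, 10, 50} (a log-spaced discretization of
the 0.01–50 range) × {linear, poly, rbf, sigmoid} kernels, one-vs-rest with
arg-max decision aggregation; RF depth {5, 10, 20, 30, 40} ×
max_features {20, 30, 40, 50, 60}, with candidates exceeding the feature
dimension skipped (all infeasible → fall back to the dimension itself).
Selection is by mean 10-fold stratified CV accuracy; ties break to the
first candidate in grid order; the winner is refit on all training rows.
If the rarest class has fewer rows than folds, the fold count drops to
that class count with a warning.

Features are z-scored inside the pipeline for k-NN and SVM (distance- and
kernel-based methods are scale-sensitive and the FFT/wavelet features span
orders of magnitude); forests consume raw features. Scaling parameters are
always fit on the training partition only.

* **Intra-subject**: per subject, a stratified 80/20 split (per class,
  round(0.2·n) test rows, at least 1), tuning on the 80 %. Headline
  metrics are unweighted means over subjects; dispersion is the sd across
  subjects.
* **Inter-subject**: subjects are partitioned into 5 balanced random folds
  (37 subjects → sizes 8/8/7/7/7); each fold is the test set once, and
  tuning happens inside the pooled training subjects, so no information
  from test subjects leaks into model selection. Metrics are unweighted
  means over the five repetitions.

On each test partition, overall accuracy equals trace/sum of the confusion
matrix (the micro-averaged recall identity is asserted at construction).
The aggregated report's headline accuracy is the unweighted mean across
units, which coincides with the pooled ratio only when units contribute
equally many windows; both the per-unit accuracies and the summed
confusion matrix are retained.

## Model comparison

The replicate unit for the ANOVA is the inter-subject fold accuracy (five
per cell) — the only replicate structure the protocols expose. Per window
length, a fixed-effects two-way ANOVA with interaction is fit (via OLS;
the design is balanced and complete, which is validated, so type I/II/III
sums of squares coincide). Tukey HSD compares factor-level means with
`q = |Δmean| / sqrt(MS_resid / n)` against the studentized range
distribution, using the residual mean square and degrees of freedom from
the two-way model. The studentized-range tail probability comes from
`scipy.stats.studentized_range`; the test suite cross-checks it against a
direct numerical quadrature of the defining double integral.

## Interpretation

* **Overall importance**: normalized mean-impurity-decrease from the
  random forest, reported in full for the 27 time features and truncated
  to the top 30 (frequency) / 15 (time–frequency) elsewhere.
* **Local surrogate** defaults: 5000 Gaussian perturbations in
  standardized feature space (scales = background sd), kernel weight
  exp(−d²/κ²) with κ = 0.75·√d, ridge penalty 1.0, selection of the
  largest-|coefficient| features followed by a refit on the selected set.
  All are configurable; a constant model output over the neighborhood
  yields a zero-weight explanation with a flag rather than noise. The
  surrogate needs a model with a *graded* class score over the
  neighborhood: a 1-NN's 0/1 probability is typically flat there, so
  class-specific analyses use a larger neighborhood (e.g. k = 25) or
  another score-producing classifier.
* **Class-specific importance** averages the surrogate weights over up to
  30 correctly classified windows of the class; each observation's
  perturbation seed derives from its row index, making the average
  independent of visiting order.
* **Reconstruction**: for frequency features, the selected bins (with
  conjugate-symmetric partners implicit in the rFFT representation) are
  kept and everything else zeroed before the inverse FFT — selecting all
  bins reproduces the signal to 1e−9. For wavelet features, every band
  containing at least one selected feature is kept whole (band statistics
  derive from whole bands) and the inverse DWT is exact to 1e−8.

## Problem sizes used in the test suite

Unit tests run on a 5-subject cohort with 40 s per task; the end-to-end
recovery property uses 10 subjects at full task durations (156 ten-second
windows each), time–frequency features, and a reduced forest grid
(depth {10, 30}, max_features 20, 50 trees) — small enough to run on one
CPU in minutes while leaving the recovery thresholds (intra ≥ 0.90,
inter ≥ 0.85) large margins. ANOVA type-I calibration uses 1000 simulated
null tables.

## Known limitations

* The synthetic cohort is a structural stand-in; accuracy numbers obtained
  on it say nothing quantitative about field performance.
* Windows crossing annotation boundaries are dropped, not truncated;
  change-point-based segmentation for mixed task schedules is out of
  scope.
* The entropy/crossing definitions and the FFT-magnitude convention are
  documented choices among several in use.
* LIME-style explanations on k-NN class scores degrade when the score is
  locally flat; the constant-output flag makes this visible rather than
  silently returning zeros.
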