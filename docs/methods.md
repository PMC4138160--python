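# Methods

`gaitsep` implements a classification-oriented analysis of bilateral lower
extremity running kinematics: it asks whether two runner sub-populations
(female vs male, overall and within age bands) are linearly separable in the
space of discrete stance-phase joint angles, and which principal components
carry that separation. This note records the model, the choices that were
genuinely open, and what the synthetic cohorts do and do not emulate.

## The pipeline

**Events and normalization.** Initial contact is detected on the superior
calcaneal marker's vertical-velocity channel as a positive-to-negative
crossing; the reported index is the first sample at or below zero (the
crossing definition only fixes the transition, so one of the two adjacent
samples had to be chosen; the first non-positive sample makes the detected
instant the first moment the foot is provably descending-to-loaded). A
refractory period (default 0.2 s, shorter than any stride at 2.2–3.4 m/s)
suppresses noise-induced double crossings. Toe-off is the minimum of the
knee sagittal channel (peak knee extension) searched from each contact to
the next contact — the search window is a choice, since peak extension is
only meaningful within a stance-to-swing transition; ties take the first
occurrence and a boundary minimum emits a warning. Each stance is resampled
to 101 points (0–100% of stance) by piecewise-linear interpolation
(monotone, overshoot-free); a cubic-spline option exists but can overshoot
near sharp peaks. Endpoints reproduce the raw samples at contact and
toe-off exactly.

**Stride aggregation.** Whether the discrete variables should be computed
per stride and then averaged, or computed once from an ensemble-averaged
stance waveform, is underdetermined; both are provided and the ensemble
average is the default (it attenuates additive noise by 1/sqrt(n_strides)
before the nonlinear extrema extraction, which is the less biased order for
noisy signals). For noiseless waveforms the two coincide.

**Discrete variables.** For each of 18 channels (2 sides × {hip, knee,
ankle} × {sagittal, frontal, transverse}) four scalars are taken: angle at
touchdown (0%), maximum peak, minimum peak, and angle at toe-off (100%),
giving 72 variables. Peaks are taken over the closed 0–100% interval, so a
monotone waveform's peaks sit at its endpoints.

**PCA.** Columns are standardized to zero mean and unit sample SD (divisor
n−1); the sample covariance of the standardized matrix (= the correlation
matrix of the raw table) is eigendecomposed; scores are the standardized
matrix times the eigenvector matrix. With n subjects and 72 variables the
numerical rank gives min(72, n−1) components (483 → 72, 56 → 55, 51 → 50).
Eigenvector sign is arbitrary, so each eigenvector is flipped to make its
largest-magnitude loading positive; this affects nothing downstream (effect
sizes are ranked by magnitude) but makes every serialized artifact
reproducible. Components below 1e−10 of the leading eigenvalue are dropped
as numerical noise.

**Effect-size ranking.** For each PC score column, Hedges's g =
(mean_female − mean_male) / s_pooled, with s_pooled the usual
pooled-variance estimate and the small-sample correction
J = 1 − 3/(4N − 9) applied by default (at N = 483 it changes g by < 0.2%,
at N = 51 by ~1.5%). PCs are ordered by |g| descending; ties break by
variance explained, then index. The sign convention (female − male) is
cosmetic. Magnitude labels: large ≥ 0.8, medium ≥ 0.45, small below — the
medium cut is set at 0.45 rather than the conventional 0.5 so that values
in the high 0.4s, conventionally discussed as medium effects in this
literature, are labelled consistently.

**Classification.** A linear-kernel soft-margin SVM (penalty c = 1) is
evaluated by ten-fold cross-validation: subjects are randomly partitioned
into folds of size ⌊n/10⌋ or ⌈n/10⌉ (483 → 49,49,49,48×7), each fold serves
once as the test set, and the unweighted mean of the ten fold accuracies is
reported. Folds are not stratified by class by default (plain random
partition); stratification is available. The accuracy-vs-k curve evaluates
every prefix of a PC ranking with one fold assignment shared across k, so
the variance- and effect-sorted curves differ only in column order.
"Repeating the procedure 10 times" is read as the ten fold evaluations of a
single partition; independent re-randomized repetitions are available via
`n_repeats`.

**Leakage.** By default the PCA and the effect-size ranking are fitted on
the full sample before cross-validation, reproducing the classical order of
operations (decompose first, then partition). This leaks test-subject
information into the feature construction and flatters absolute accuracy;
`accuracy_curve_leakage_free` (and `leakage="fold_internal"` in the
pipeline config) refits standardization, PCA and ranking inside every
training split and projects the held-out subjects through them. The two
modes answer different questions — "how separable are these subjects in
their own PC space" vs "how well would this procedure classify a new
runner" — and both are first-class.

**Prefix selection.** Two rules: smallest k maximizing mean CV accuracy,
and the largest prefix whose every PC has |g| strictly above a threshold
(default 0.09, matching the observed scale below which added PCs stop
helping). Both are reported; neither feeds back into the ranking.

**Group statistics.** Per-variable two-sample t-tests use the
pooled-variance statistic by default (Welch by flag); p-values are adjusted
by the Holm step-down procedure (via `statsmodels`) with the family equal
to all tested variables. PC–variable association uses Pearson correlation
magnitudes with categories weak / moderate (|r| ≥ 0.36) / strong
(|r| > 0.67); signed values are retained in the serialized output.

## Synthetic cohorts

No subject-level data are packaged; cohorts are drawn from per-group
multivariate normals whose per-variable means and SDs are transcribed from
the published group statistics (26 side-specific variables carry
gender-specific printed values in the general cohort, 20 in the young and
12 in the older subgroup; the rest use documented gender-neutral defaults
chosen as typical recreational-running stance values, identical for both
groups, and subgroup fixtures inherit general values where no subgroup
value was printed — every fixture entry carries a `source` tag).

**Correlation model.** The publication reports no between-variable
covariance, so any choice is a modeling decision. The default couples each
left/right variable pair at ρ = 0.6 (pairs mutually independent):
bilateral symmetry is the one redundancy the data certainly contain, and
fully independent columns would understate the structure PCA exploits.
Independent and user-supplied correlation matrices are also supported.

**Ages.** Group sizes are 220 male / 263 female. Ages are drawn from a
three-stratum mixture — 16/170/34 males and 40/206/17 females uniform in
18–26, 26.5–54.5 and 55–72 years respectively — so that the closed age-band
filters reproduce the published subgroup compositions (56 = 16 + 40 young,
51 = 34 + 17 elderly) exactly rather than in expectation. Height and mass
are not generated; nothing downstream uses them.

**What passing tests show.** The synthetic cohorts match the published
first and second marginal moments and the published group directions, but
they are Gaussian, they impose an invented correlation structure, and the
gender contrast they encode is spread over 26 variables with no
within-group heterogeneity (injury status, speed, footwear). Consequently
the synthetic general cohort is *more* linearly separable along its leading
PC than real runners are: the top effect size lands on a low-order PC,
whereas in real data the discriminative directions sit mid-spectrum. Tests
on these cohorts validate the machinery (calibration, ranking logic,
cross-validation contracts), not the biomechanical claim; the planted-signal
tests, which bury the group contrast deep in the spectrum by construction,
are the ones that exercise the scenario the effect-size ranking was designed
for.

**Stride simulator.** Defaults emulate treadmill running at a self-selected
pace: 35 strides of 0.6 s at 200 Hz with a 38% stance fraction. Stance
waveforms are monotone (pchip) interpolants through the four control values
(touchdown, max peak with timing, min peak with timing, toe-off), so stance
extrema equal the control values exactly and extraction can be checked
against them; the knee sagittal shape places its minimum at toe-off, which
is what makes the toe-off event definition self-consistent. The calcaneal
velocity channel is built with integer phase arithmetic so the planted
contacts are exactly the positive-to-negative crossings, deterministically.
Swing-phase trajectories are schematic (a single mid-swing flexion bump);
only stance is analyzed.

## Numerical choices and problem sizes

- Eigendecomposition via `numpy.linalg.eigh` on the explicit correlation
  matrix; tests cross-check eigenvalues, eigenvectors and scores against an
  SVD of the standardized matrix at 1e−8.
- Zero-variance columns abort standardization with the column named.
- Default test and acceptance runs use the published cohort sizes (483/56/51
  subjects, 72 variables, full accuracy curves with 10 folds); the complete
  acceptance script runs in well under a minute on one core.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds carried in specs/configs; two runs with the same configuration
  produce byte-identical summary JSON (floats are rounded to 10 decimals at
  serialization only).

## Known limitations

- The marker-to-angle computation (3D kinematics from motion capture) is out
  of scope; inputs start at joint-angle time series or feature tables.
- No kinetics, no swing phase, no injury-status modeling, no multi-class
  extension of the effect-size ranking (it is strictly two-group).
- The quadruple ordering invariant (min peak ≤ touchdown/toe-off ≤ max peak)
  holds for extracted tables but cannot be imposed on cohorts drawn
  variable-by-variable; validation exposes it as an opt-in check.
- Absolute cross-validated accuracies on synthetic cohorts reflect the
  generator's assumptions, not running biomechanics, and the default
  full-sample ranking mode overstates out-of-sample accuracy by design (see
  Leakage above).
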