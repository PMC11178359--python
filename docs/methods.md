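# Methods

This note documents the models, numerical choices and validation logic of
`socialgrid`, and what the synthetic-data results do and do not show about
real data.

## Task and signal model

The simulated task is a recall paradigm on a unit-square map whose axes
are two bounded trait dimensions (competence, trustworthiness). Each
trial is a trajectory vector: a direction θ ∈ [0, 2π) and a Euclidean
distance d. A block holds `n_trials` (default 80) trials whose directions
are sampled one per equal-width bin of the circle, so every 4.5° bin is
occupied exactly once; presentation order is shuffled. Half of the
trajectories terminate exactly on one of six avatar landmarks (the start
is back-computed as end − d·(cos θ, sin θ), with d drawn uniformly from
`distance_range` restricted to the admissible interval that keeps the
start inside the square); the other half terminate away from all avatars.
Avatar layouts are jittered uniformly within 1/30-unit discs around fixed
centers; an avatar counts as reached within a 0.01-unit pop-out radius.

Trial timing: a 2 s morph stage (1 s watched movement + 1 s imagined
continuation at the same speed) followed by a 2.5 s choice stage and a
jittered 2–6 s inter-trial interval, with 10 s padding at both run ends.
The choice-stage duration and ITI are not constrained by the task design
itself; the defaults were chosen to keep the design matrices
well-conditioned and are configurable.

BOLD generation: per-trial neural amplitudes are

* grid voxels — `morph_amplitude + ω·cos(f(θ − φ_v))` during the morph
  stage (f = 6 by default),
* distance voxels — `morph_amplitude + slope·d`,
* noise voxels — no task response,

plus a choice-stage response, a constant offset (100, so that tSNR is on
a realistic scale), convolution with a canonical double-gamma HRF sampled
at TR = 2 s, and additive white Gaussian noise (optional AR(1) behind
`ar1_coef`). Overlapping events sum linearly. Per-voxel grid phases φ_v
are von Mises on the folded angle, ψ_v = 6φ_v ~ VM(6φ, κ = 4), encoding
the assumption that neighbouring grid populations share similar
orientations (κ = 4 puts ~90% of voxel orientations within ±8° of φ)
while leaving enough dispersion for multivariate pattern structure.

**Contrast-to-noise calibration.** The validation regime is defined by
the per-voxel sensitivity of the quadrature F-test: with ω = 1 and the
default 4-run × 80-trial design, `noise_sd = 12` puts the median
per-voxel quadrature Z at ≈ 2 (measured by simulation and frozen as the
generator default). All recovery and power results below are statements
about this regime.

Every generator is a pure function of (config, seed); per-run and
per-subject streams are spawned from a root `SeedSequence`.

## GLM machinery

Stage regressors are boxcars whose duration equals the modelled stage,
convolved with the peak-normalised double-gamma HRF on a 50 ms grid
(Riemann-scaled, so a unit-amplitude 2 s event yields an O(1) response)
and sampled at frame times k·TR. Parametric modulators (sin fθ, cos fθ,
distance) are mean-centered per run *before* convolution; no serial
orthogonalisation is applied. Slow drifts: discrete-cosine basis with a
128 s cutoff plus an intercept. Estimation is plain OLS per voxel;
multi-run fits concatenate runs with shared task/modulator columns and
run-specific drift/intercept blocks, so a single (β_cos, β_sin) pair and
an F(2, df) statistic exist per voxel. All-zero (degenerate) columns —
empty direction bins, constant modulators — are dropped from fitting and
flagged; a rank-deficient remaining design is an error naming the
collinear columns.

F→Z: Z = Φ⁻¹(P(F′ ≤ F)) computed through the survival function for tail
accuracy and clipped at |Z| = 8.2 where the probability saturates. Under
the null this makes Z standard normal, which the test suite verifies
empirically (2000 noise voxels; type-I error within [0.035, 0.065] at
α = 0.05, Kolmogorov–Smirnov sanity check).

## Orientation and consistency

φ = atan2(β̄_sin, β̄_cos)/f over ROI-averaged betas, reported on the
fold's fundamental domain [0°, 360°/f); a near-zero resultant is flagged
low-confidence rather than erroring. Trials are binned by (θ − φ) mod
360° to the nearest of 2f centers k·360°/(2f) with half-open bins (an
offset exactly at a bin edge, e.g. 15° for f = 6, rounds up); even bins
are aligned. The consistency contrast renormalises over occupied bins:
mean(occupied aligned) − mean(occupied misaligned). A held-out run with
an empty class is excluded with a warning.

The cross-validation fits GLM2 per held-out run and averages the four
run contrasts into the subject-level effect (rather than fitting one
GLM2 over the concatenated testing sets); this keeps the orientation
used for a run strictly independent of that run's data, which the test
suite verifies by perturbation. Group inference is a one-sample t-test
(directional by default, matching the aligned > misaligned prediction);
fold specificity uses paired t-tests of the fold-6 contrast against each
control fold (4, 5, 7, 8). Covariate analyses are simple per-covariate
regressions with Benjamini–Hochberg FDR across covariates. ROIs are
voxel-index lists; a sphere-around-peak utility (`sphere_roi`) replaces
atlas/peak-sphere machinery.

## RSA

LSS: per trial, one target regressor, one nuisance regressor carrying
all other morph events, the choice regressor, drift and intercept; the
target beta is the trial's pattern row. Dissimilarity is 1 − Pearson r
(the metric is configurable in principle but not spec-critical; Pearson
is the field default). The model DSM is the angular difference folded by
360°/f, range [0°, 180°/f]. The orientation-independent statistic is the
Spearman correlation over one off-diagonal triangle (within-run pairs
can be excluded with a flag), Fisher-Z transformed for group inference.
The orientation-dependent statistic classifies each run's trials with
that run's leave-one-out orientation and takes mean(AA) − mean(AM)
similarity, pooled over runs by default (a within/across-run toggle
exists because the pooling convention is a genuinely open choice).

At the calibrated univariate CNR (per-voxel Z ≈ 2) the AA−AM difference
computed through the full BOLD→LSS route is dominated by single-trial
estimation noise and is not reliably positive — an informative fact
about the fragility of orientation-dependent RSA at realistic
sensitivity. The RSA statistics are therefore validated on generatively
hexadirectional *patterns* (`simulate_trial_patterns`: the same cosine
tuning and phase-dispersion model, expressed directly at the pattern
level with unit pattern noise), where both statistics are positive at
the group level and centered on zero under ω = 0 or direction
permutation.

## Circular statistics

Angles are folded (ψ = fφ mod 2π) before testing. V-test:
V = n·R̄·cos(θ̄ − μ0) with μ0 the fold-transformed ROI-mean orientation
from the same estimating set (the "neighbouring grid cells share
orientation" hypothesis fixes the mean direction). Rayleigh: R̄ with
Zar's small-sample-corrected p. For n ≤ 10 both tests use a seeded
Monte-Carlo uniform null (200k draws; the reference distribution depends
only on the statistic and n, so both tests remain exactly rotation
invariant): a Monte-Carlo study during development showed the V-test
normal approximation can err by more than 0.01 at n = 10, while both
approximations are accurate to ~10⁻³ for larger n.

## Behavioral indices

Occupancy uses half-open 15×15 cells (top/right boundary closed at 1.0);
edge cells are the outermost rows/columns (56 of 225). Time at avatars
counts samples within the pop-out radius. Collect metrics use strict
thresholds (< 15°, < 0.01 units). Distance-effect indices are
per-participant OLS slopes of log-RT and accuracy on the task-relevant
distance (the pairwise separation on the compared axis, or the
expected-profit difference `investment·(1+c)·t` for the cooperation
block). Full mixed-effects modelling is deliberately out of scope; the
deterministic per-participant slopes serve as the exported covariates.

## QC

tSNR = μ/σ per voxel per run (σ on the raw series, matching the plain
definition; a detrended variant sits behind a flag), averaged across
runs; σ = 0 voxels are flagged undefined and excluded from ROI means.
The tSNR–modulation relation is computed across subjects (Pearson on
subject means) and within subjects (voxelwise r, Fisher-Z, two-sided
Wilcoxon signed-rank at the group level).

## Validation problem sizes

The acceptance script and tests use: 20 subjects × 4 runs × 80 trials
with a 50-voxel grid ROI (20 distance, 30 noise voxels) for orientation
recovery, consistency and fold specificity; 100 repetitions of a
scaled-down null cohort (10 subjects, 4 runs × 24 trials, 8 voxels,
ω = 0) for the type-I calibration of the group test; one 2000-voxel
noise run for F→Z calibration; 20 pattern-level subjects for RSA. These
sizes give stable Monte-Carlo estimates while keeping the whole
validation in the low minutes on one CPU.

## Known limitations

* White (or AR(1)) noise only — no physiological confounds, motion, or
  spatial autocorrelation; voxels are independent. Passing tests show
  the estimators are correct and calibrated under the stated model, not
  that real EC/PFC data will yield detectable effects.
* The BOLD grid signal is exactly sinusoidal in 6θ; real grid-like
  signals may deviate (e.g. amplitude differences between axes).
* No whole-brain inference: cluster-level FWE, searchlights and
  smoothing are out of scope; analyses operate on voxel lists.
* LSS assumes the two-regressor (target/rest) decomposition is adequate;
  very short ITIs would need fancier single-trial estimators.
* The recall-task foil construction and response model are minimal
  (fixed per-trial correctness probability) — adequate for accuracy
  bookkeeping, not for modelling choice behaviour.
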