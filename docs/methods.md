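# Methods

## Coordinate and voxel conventions

All volumes are NIfTI-1 with a 4×4 voxel→world affine; all tractograms are
TCK with points in scanner-space millimetres (TRK and other dialects are
out of scope — one unambiguous coordinate convention). Every distance used
internally is physical (mm), never voxel units, so anisotropic and oblique
grids behave correctly; the 1 mm prior-mask dilation is a Euclidean
distance between voxel centres measured through the affine.

A continuous voxel-space coordinate belongs to the voxel whose centre is
nearest (round-half-up per axis, `floor(x + 0.5)`), i.e. voxel `i` owns the
half-open cube `[i − 0.5, i + 0.5)`. Masks read from file are binarized at
> 0.5, tolerating interpolation artefacts from cross-space registration.
Registration itself is out of scope: inputs are assumed co-registered.

## Streamline–voxel geometry

Two visitation semantics are implemented:

- **exact** (default): the set of voxels whose cube the streamline
  polyline passes through, found by enumerating half-integer boundary
  crossings segment by segment. This is the continuum limit of ever-denser
  point sampling and is independent of any resampling resolution.
- **points**: voxels receiving at least one point after uniform arc-length
  resampling at spacing ≤ `step` (default half the smallest voxel
  dimension, which prevents a segment skipping across a voxel by more than
  a corner clip).

The exact mode exists because two *different* dense point samplings of the
same curve disagree, with non-negligible probability, on voxels the curve
clips for less than the sampling interval; in randomized experiments a
0.01 mm sampler differed from the continuum on ~13% of smooth streamlines
crossing a 1 mm grid. Point sampling at any finite spacing therefore
cannot serve as a reference semantics, only as a lower bound (every
sampled point lies on the polyline, so its voxel set is always a subset of
the exact set — asserted in the tests). The test suite validates the exact
traversal against an independent brute-force oracle that applies a
segment/box (slab) intersection test to every candidate voxel.

Out-of-grid travel contributes nothing and raises nothing: resection masks
and scalar maps legitimately cover a subvolume of the bundle's extent.

Derived operations: per-voxel visitation counts; the bundle probability
map (counts ÷ streamline count) thresholded at 0.01 to form bundle masks;
the transection fraction (a streamline is cut iff it visits any set mask
voxel; ties `percent_cut = 100·(n_pre − n_post)/n_pre`); the cohort
overlap atlas (per-voxel fraction of subjects, values exact multiples of
1/n); the disconnection probability (maximum atlas value over resected
voxels, 0 on disjoint support, binarized at 50% with ties counting as
disconnected); median FA/MD over the *distinct* voxels the bundle visits
(one vote per voxel, so long streamlines do not overweight their voxels —
the per-point alternative would weight by arc length); and normalized
(÷ ICV) plus cohort min-max rescaled bundle volumes (a constant cohort
rescales to all zeros with a warning rather than 0/0).

## Reliable change index

Change scores (post-z − pre-z; missing timepoints stay missing, never
zero-filled) are regressed per task and postoperative timepoint on age at
surgery, normalized resection volume and the preoperative z-score
(z rather than raw, so the covariate shares the response's scale). The
regression is an MM estimate: a 50%-breakdown S-estimate (Tukey bisquare,
c = 1.5476, E ρ = 0.5) obtained from seeded p-subset sampling with IRWLS
refinement provides the initial coefficients and the robust residual
scale; a redescending bisquare M-step (c = 4.685, 95% Gaussian efficiency)
at that fixed scale gives the final fit. The estimator is deterministic
given the data (fixed subsampling seed), collapses to OLS on exactly
interpolable data, and is cross-checked against `MASS::rlm(method="MM")`.

The 80% confidence interval is taken as the two-sided normal-theory
interval on residuals with the robust scale, so the lower limit sits at
the 10th percentile, −z₀.₉₀·σ̂ ≈ −1.2816·σ̂; a residual strictly below is
classified −1. The empirical-residual-quantile variant is available via
`method="empirical"`. A one-sided reading of "80%" (limit at the 20th
percentile) would flag ~20% of a Gaussian cohort; the two-sided reading
was chosen as the standard regression-based RCI construction, and the
calibration test pins the ~10% rate. Rows with missing change scores or
covariates are excluded from the fit but retained (NaN) in the cohort
table.

Normative data for the memory instruments are not redistributable; the
package ships a clearly-labelled synthetic normative table (age-banded
means/SDs of plausible magnitude for a 75-point list-learning total and a
15-point delayed recall) and accepts user tables as CSV
(`task, age_low, age_high, mean, sd`).

## Harmonization

Each feature is compared between the two scanner batches with a Welch
two-sample t-test (Welch–Satterthwaite df); only features significant at
α = 0.05 are adjusted — configurable, and deliberately a *gate*, since
adjusting null features costs degrees of freedom. Adjustment is the
standard ComBat location-scale model: per-feature standardization on
covariate-adjusted data, per-batch additive (γ) and multiplicative (δ)
effects with parametric empirical-Bayes shrinkage across features (normal
prior on γ, inverse-gamma on δ, method-of-moments hyperparameters,
iterative conditional-posterior solution), then covariate effects and
scale restored. Age at surgery and age at onset are preserved as
covariates by default. With `eb=False` the raw per-batch estimates are
used, which aligns batch means and residual variances exactly — the limit
used by the exactness tests. With a single gated feature EB shrinkage has
no cross-feature information and falls back to the raw estimates. The EB
path reproduces `sva::ComBat(par.prior=TRUE)` to ≤ 1e-6.

## Outcome models

The longitudinal model for change-from-baseline z-scores is a linear mixed
model with a random intercept per subject, fitted by **maximum
likelihood** (not REML) so that likelihood-ratio comparisons of fixed
effects between nested models are valid. Fixed effects: timepoint as a
factor with the 3-month visit as reference (so the 12-month coefficient
directly expresses recovery relative to 3 months), age at surgery, age at
onset, resection volume, preoperative score, and optionally one tract term
(transection fraction on the 0–1 scale, disconnection status, or rescaled
remaining volume). Rows with missing outcomes are dropped; subjects
contributing a single timepoint remain. Non-convergence is reported via a
flag, never silently. Exactly interpolable (noise-free) data make the ML
profile unbounded in the residual variance, so that degenerate limit
returns the interpolating OLS solution explicitly.

The LRT is χ² = 2(ℓ_full − ℓ_null) with df = the difference in fixed
effects, clamped at 0 against boundary numerical noise; identical models
give χ² = 0, p = 1.

Binary outcomes (RCI decline across the two postoperative timepoints) use
a logistic random-intercept model whose marginal likelihood integrates the
intercept out with 21-node Gauss–Hermite quadrature, maximized with BFGS
(Nelder–Mead retry from a cold start). Complete separation is detected on
the unpenalized logistic fit and handled by a small ridge penalty
(flagged, not silent). For one-observation-per-subject outcomes (ILAE
seizure freedom at 12 months, binarized as class 1 vs > 1) the random
intercept is unidentifiable and the model reduces to plain logistic
regression with the variance pinned at 0.

## Synthetic cohort

The generator emulates the *statistical structure* of a left
anterior-temporal resection cohort, not its anatomy or dMRI physics:

- **Bundle**: 30 streamlines per subject (Catmull-Rom curves through 5
  jittered control points, 40 evaluation points) sharing a posterior trunk
  and fanning to anterior-inferior terminations; the fan's anterior reach
  varies per subject (fan centre uniform on 31–45 mm, half-span 14 mm), a tube radius of 1.5 mm, per-control-point jitter of
  0.8 mm and whole-subject spatial jitter of 1 mm.
- **Cavity**: an ellipsoid at the anterior-inferior corner of the bundle's
  territory whose posterior radius is uniform on 1–30 mm and whose
  width/height vary independently (8–16 / 7–14 mm), clipped at the grid
  edge as real resections reach the brain surface. Deeper cavities
  transect a larger share of the fan; under the defaults the cohort's
  transection fractions span at least 5–80% (a tested invariant), and the
  independent width/height variation keeps resection volume from being
  collinear with transection (r ≈ 0.75), which is what gives the
  mixed-model tract term identifiable leverage.
- **Scores**: preoperative z ~ N(−0.5, 0.9); change = 0.2 + 0.25·𝟙(12 m)
  − 0.01·age − 3·resvol − 0.25·pre − 0.5·transection + u + ε with
  u ~ N(0, 0.2²) per subject and ε ~ N(0, 0.28²) — noise magnitudes
  consistent with a high-reliability instrument, chosen once by power
  analysis so that an n = 80 cohort detects the built-in effect. The
  3-month visit is worse than 12 months by construction (recovery term).
  Raw scores are reconstructed through the synthetic normative table and
  clipped to the instrument maxima (75 / 15).
- **Batches**: two scanners assigned Bernoulli(½); FA maps shift by
  +0.04, MD by +3·10⁻⁵ mm²/s on the second scanner, on top of smooth
  bundle-contrast maps with Gaussian noise.
- **Seizure outcome**: P(ILAE = 1) = expit(−0.3 + 1.0·transection);
  non-free subjects draw a class from 2–5.
- **Missingness**: 6% of 3-month and 12% of 12-month scores.

Randomness: every subject derives its streams from
`SeedSequence(master_seed, spawn_key=(subject_index,))`, so cohorts are
bit-reproducible and extendable without changing existing subjects. The
ground-truth sidecar stores every component (coefficients, random
intercepts, per-score noise, true transection fraction); a test
reconstructs each simulated score exactly from it.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: realistic brain anatomy or partial
voluming, dMRI signal formation and tractography failure modes (the
streamlines are clean curves, not probabilistic reconstructions),
instrument differences between test versions, non-Gaussian score noise,
and informative missingness.

## Problem sizes used in validation

The statistical validation suite uses cohorts of 80 subjects (100
replicates for effect recovery and power, 100 for null rejection), 40
subjects × 200 replicates for the null-LRT distribution check, and 200
robust-regression cohorts of n = 150 for RCI calibration — sizes at which
the Monte-Carlo error of each checked quantity is several times smaller
than its acceptance band.

## Known limitations

- The Tractotron probability uses the raw (unsmoothed) atlas and the
  literal maximum rule; no spatial regularization.
- The Welch gate tests exactly two batches; cohorts spanning three
  scanners must be harmonized pairwise or with the gate disabled.
- The GLMM's quadrature assumes a single random intercept; nested or
  crossed random effects are out of scope.
- Streamline counts, not fibre counts: transection fractions inherit all
  biases of the upstream tractography.
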