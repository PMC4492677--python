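# Methods

## Model

Expression of gene *n* (of *N*) at time point *t* (of *T*) is modelled as

    y[n,t] = mu[n] + sum_m X[n,m] b[n,m] c[m,t] + eps[n,t],
    eps[n,t] ~ N(0, sigma^2) i.i.d.

with `X` the fixed binary gene × TF regulon-membership matrix, `b` the
gene-specific regulatory strengths (nonzero only where `X = 1`), `c` the
latent TF activity profiles and `mu` per-gene baselines.  Strengths are
free-signed: whether a TF activates or represses a given target is learned
from the data, and any `sign` column in the connectivity file is kept for
provenance only.

Priors:

* `b[n,m] ~ N(0, strength_prior_sd^2)`, default SD 1;
* `mu[n] ~ N(0, baseline_prior_sd^2)`, default SD 1;
* per TF, a Gaussian random walk over the actual minute grid:
  `c[m,t_1] ~ N(0,1)` and `c[m,t_k] ~ N(c[m,t_{k-1}], rw_scale^2 * dt_k)`.
  `rw_scale` has units of activity per √minute; the default 0.1 makes the
  marginal prior SD after a 110-minute experiment about 1, consistent with
  the unit-scale prior on the first time point.  The random walk encodes
  that activities evolve smoothly, with larger possible excursions across
  larger sampling gaps.

`sigma` is a single noise scale shared across genes — the simplest variant
defensible for very short (five-point) series.  A per-gene noise scale is
available behind the `per_gene_noise` flag for long series or strongly
heteroscedastic data.

## Inference

The posterior is approximated by mean-field variational Bayes factorising
as `q(b, mu) q(c)`:

* `q(theta_n)` — one joint Gaussian per gene over `(mu_n, b_n·)`, so
  baseline/strength and strength/strength correlations within a gene are
  retained;
* `q(c_m)` — one joint Gaussian per TF over the full time grid, retaining
  the random-walk correlation across time; TFs are independent under `q`;
* `sigma^2` — closed-form point update (expected residual sum of squares
  over `N·T`), floored at 1e-12 to keep noiseless inputs numerically safe.

Each sweep performs exact coordinate updates (all `q(c_m)` sequentially,
then all `q(theta_n)`, then `sigma`), so the evidence lower bound is
non-decreasing by construction; the trace is stored on the returned
posterior and asserted monotone (tolerance 1e-8) throughout the test suite.
Per-gene updates are batched over genes with the same regulon size, so a
sweep is a handful of stacked small-matrix operations.

Plain coordinate ascent on this model creeps: the likelihood is exactly
invariant under `(b_j, c_j) -> (a b_j, c_j / a)` per TF, and only the
priors weakly pin that direction, so successive sweeps drift slowly along
it.  Each sweep therefore includes an additional exact ascent step in this
direction: the ELBO as a function of `a` has a closed-form maximiser
(solving `P u^2 − (G−T) u − Q = 0` for `u = a^2`, where `P` is the expected
squared strength mass over the TF's `G` targets scaled by the strength
prior, and `Q` the expected random-walk quadratic form of the activity).
This preserves monotonicity while removing the slow mode; convergence
(relative ELBO change below `elbo_rel_tol`, default 1e-6, checked after
sweep 2) typically takes a few hundred sweeps instead of many thousands.

Initialisation is deterministic given the seed: activities start at zero,
baselines at gene means, strengths at small seeded Gaussian draws (the
asymmetry that breaks the all-zero fixed point).  Non-convergence within
`max_iters` returns the fit with `converged = False` and a warning rather
than an error.

### Gauge

The bilinear form leaves each TF's sign and scale undetermined.  After
convergence the returned solution is normalised: each TF's strength vector
is scaled to unit Euclidean norm (activities and their variances absorb the
scale) and the sign is flipped so the largest-magnitude strength entry is
positive.  Refits from different random initialisations then agree to
better than 1e-3 median absolute activity difference on the standard
fixture (this check uses a tightened `elbo_rel_tol` of 1e-10, since at the
default tolerance the residual disagreement is convergence error, not gauge
ambiguity).

A residual quasi-degeneracy remains between the baselines and the constant
component of an activity profile (a constant can shift between `mu` and
`c` at small prior cost).  The priors resolve it deterministically, but
users comparing a fitted profile against an external reference should
compare either up to a constant offset or with the baseline prior tightened
when the baseline is known to be zero.

## Coherence statistics

For a TF fitted under conditions A and B, with posterior-mean profiles
`a, b` over the shared time grid:

* profile difference `x = 1 − |Pearson r(a, b)|` — invariant under affine
  rescaling and sign flips of either profile;
* magnitude difference `y = | ‖a‖₂ − ‖b‖₂ |` — norms over the raw activity
  values with no time weighting.

Uncertainty propagation is Monte Carlo over the marginal posteriors:
`n_draws` (default 1,000) paired draws per condition give the mean and SD
of `|r|` and the SD of the draw-wise magnitude difference.  The x error bar
equals the SD of `|r|` (since `x = 1 − |r|`); the y error bar is the
magnitude-difference SD.  Point coordinates always come from the
posterior-mean profiles; draws feed only the uncertainty columns.

A TF whose posterior-mean profile is exactly flat has an undefined Pearson
correlation; it is excluded from the table and listed in the side report —
no surrogate value is invented.  Quadrants partition the plane at
`x_split` (default 0.5) and `y_split` (default: median magnitude difference
over plotted TFs, since no natural absolute scale exists for activity
norms): C = similar in both respects (near origin), A = similar kinetics
but different amplitude, D = different kinetics but similar amplitude,
B = different in both.

## Fold-change computations

Expression ratios are stored internally as log2 values; the significance
rule operates on the ratio scale with inclusive thresholds: up iff
fold change ≥ 2, down iff ≤ 0.5, else unchanged.  Heat-map values are
`ln(fold change)`, making up/down symmetric around zero.  Category
percentages are denominated on the genes mapped to the category
(uncategorised genes are excluded and counted in the log; a category left
empty is reported as absent, not 0%), while genome-fraction summaries are
denominated on a configurable genome size (default 4,598 genes) so that
unmeasured genes count as unchanged.  Genes listed under several categories
keep the first listed category; rows with missing expression values are
dropped, never imputed.

## Synthetic-data generator

The generator emulates a two-condition, five-time-point (10/20/40/60/120
min) bacterial stress experiment over a 16-TF panel and, by default, 4,598
genes.  Connectivity entries are i.i.d. Bernoulli (default density 0.05,
giving sparse regulons averaging a few hundred targets genome-wide per TF);
TF columns are resampled until every regulon has at least two measured
targets.  Latent activities are Gaussian random walks over the minute grid
(start `N(0,1)`, increments `N(0, dt)` with unit diffusion per minute).
Half of the panel is *coherent* (one walk copied to both conditions), half
*divergent* (independent walks), so both axes of the coherence plot carry
planted signal.  Strengths are `N(0, 1)` on connected entries, baselines
`N(0, 0.5)`, and observation noise Gaussian with default SD 0.1 — on the
log2 scale this noise is small relative to the planted signals, matching a
strong-response experiment where key transcripts change 10–1000-fold.

The generator shares the bilinear observation model with the inference
module by design, so parameter recovery is a well-posed test.  It does
*not* emulate microarray platform effects — probe-level noise structure,
dye bias, chip normalisation, censoring at the detection floor — nor
regulon misspecification (the fitted `X` is the generating `X`).  Passing
recovery tests therefore demonstrate correctness of the inference under
the model's own assumptions, not robustness to the mismatch real array
data would add.

## Problem sizes and numerical choices

The standard test fixture uses 500 genes (16 TFs, 5 time points, density
0.05, noise SD 0.1, seed 7), a scale chosen so that every regulon has
dozens of measured targets while a full two-condition fit completes in a
few seconds; the acceptance script uses the same scale.  Monte-Carlo
uncertainty uses 1,000 draws by default (SD estimates stable to well under
3/√1000).  Matrix inversions act on (k+1)×(k+1) and T×T symmetric
positive-definite matrices (k = regulators per gene, typically 0–4); the
noise-variance floor of 1e-12 is the only guard needed for noiseless
degenerate inputs.  Replicate arrays supplied as repeated time columns are
averaged before fitting.

## Known limitations

* Five time points make the Pearson correlation between two short profiles
  a coarse statistic; divergent TFs can land anywhere on the x axis and
  occasionally look moderately correlated by chance.
* The mean-field factorisation underestimates joint uncertainty across
  TFs whose regulons overlap strongly.
* Conditions are fitted fully independently (strengths are *not* shared
  across conditions), so the coherence comparison inherits two independent
  gauge choices; the correlation-based x axis is immune, but the magnitude
  axis compares norms across two separately scaled fits and is best read
  comparatively across TFs rather than absolutely.
* No TF–TF interactions, nonlinear response, or model selection over the
  connectivity; errors in the regulon map propagate directly into the
  inferred activities.
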