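# Methods

This note records the models implemented in `wildscape`, their
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.

## Synthetic study systems

The synthetic module is the package's source of test data with known
ground truth; it emulates the structure of a predator–prey field campaign
in a protected area, not any particular landscape.

**Landscapes.** Continuous predictors are stationary Gaussian random
fields: white noise smoothed with a Gaussian kernel (bandwidth 5 cells),
standardized to zero mean and unit variance.  Distance predictors are
Euclidean distance transforms of a synthetic land-cover class obtained by
thresholding the first field at a quantile — the same construction as
distance-to-habitat variables derived from a categorical land-cover map.
Default extent is a 10 × 10 km square at 100 m resolution (the working
resolution of the pipeline's predictor stack); tests use a 4 × 4 km
extent for speed.

**Occurrences.** Species points come from an inhomogeneous Poisson
process with log-intensity `Σ_k β_k z_k(x)` over the standardized layers,
sampled by rejection against the maximum intensity, so requested counts
are exact.  The reference per-species counts (`FIELD_COUNTS`: wolf 280,
wild boar 329, red deer 55, roe deer 126; 790 total) mirror a
multi-source, four-species campaign.  Records carry a date uniform over a
14-month collection window (2023-03-01 to 2024-04-30) to exercise
duplicate handling, a source label (survey / camera / roadkill /
citizen), and count 1.

**Camera encounters.** Detection counts are Poisson with mean
`t·D·v·r·(2+θ)/π` — the ideal-gas encounter rate that the REM inverts.
Defaults: density 1.2 ind/km², speed 16 km/day, radius 0.020 km, angle
0.77 rad, i.e. the same parameter regime the estimator is used in.

What the generator deliberately does *not* emulate: animal movement
trajectories and home ranges (encounters are spatially implicit),
source-specific spatial bias such as roadkill concentrating on roads,
observation error in coordinates, and imperfect detection.  Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to the violations real data bring.

## Occurrence processing

Duplicates are records sharing species, coordinates *and* date; the same
location on different dates is two records.  Thinning keeps at most one
record per species per raster cell; the paper trail matters more than the
choice itself, so the rule is deterministic: earliest date, then input
order.  Cells are half-open `[x0, x0+cs) × [y0, y0+cs)` with points on
the extent's maximum edge clamped into the last cell, so every point of
the closed extent belongs to exactly one cell.  Records are required to
be in a projected CRS in metres; the CRS is a tag, never reprojected.
The thinning grid resolution is a required parameter (the predictor cell
size, 100 m, is the natural choice); thinning intensity depends strongly
on it.

## Predictor screening

**VIF filter.** `VIF_j = 1/(1−R²_j)` from OLS of layer j on the other
retained layers (with intercept), computed on a seeded random subsample
of complete cells (default 10,000).  Removal is iterative worst-first:
while the maximum VIF exceeds the threshold (default 5), drop the worst
layer and recompute, recording every iteration.  Perfect collinearity is
VIF = +∞ and is removed first.  Iterative removal is standard practice
and avoids the over-dropping of one-shot filtering.  When removal runs
the stack down to a single layer, a final VIF is undefined; the last
recorded iteration shows the state that forced the drop.

**Bias layer.** An isotropic Gaussian kernel density of the occurrence
records, weighted by individuals observed, evaluated directly at cell
centers (a few hundred points against tens of thousands of cells needs
no approximation).  Default bandwidth 3 km.  Min–max normalization to
[0, 1] makes it a relative sampling-effort surface for background
selection; zero-density cells map to exactly 0.  Whether a bias layer is
used is a per-model flag — background sampling takes it as an optional
argument.

**Terrain.** Slope/aspect use the Horn 3×3 stencil; flat cells have
nodata aspect.  Contour extraction from any surface is an optional
polyline export feeding nothing downstream.

## The suitability model

Predictors are scaled to [0, 1] by min/max over the union of presence and
background values (stored on the model; prediction clips outside the
training range).  Feature classes: linear, quadratic, pairwise products,
and hinge — forward `max(0,(x−k)/(1−k))` and reverse `max(0,(k−x)/k)` at
20 evenly spaced interior knots per predictor.  A threshold class is
omitted: hinge features subsume piecewise-constant steps and the model
grid (`L, LQ, H, LQH, LQHP`) covers the configurations selection actually
uses.

The objective is concave; it is maximized by accelerated proximal
gradient (FISTA with backtracking line search and momentum restart), soft
thresholding against the per-feature penalties `β_j` = 1/√n for L/Q/P and
2.5/√n for hinge, scaled by the regularization multiplier.  These mirror
standard maxent defaults in spirit; the original software's
feature-count-interpolated constants are not reproduced.  Convergence:
largest weight change below `tol` (default 1e-5) or the iteration cap
(default 500, configurable); a cap hit flags the model, it does not
raise.  One-feature fits agree with a dense grid search of the penalized
objective to ~1e-7 (see the test suite), and the background mean of the
raw output is 1 by construction after every fit.

**Output transforms.** raw = `exp(λ·f − log Z_bg)` (background mean 1);
logistic = `τ·raw/((1−τ)+τ·raw)` at prevalence τ = 0.5; cloglog =
`1 − exp(−c·raw)` with `c = exp(S)/n_bg`, `S` the entropy of the
background Gibbs distribution — the standard entropy-based scaling
expressed for mean-normalized raw, so a uniform model maps to
`1 − e⁻¹ ≈ 0.632`.  Both transforms are monotone in raw, hence
rank-identical; cloglog is the default map output.

**Evaluation and selection.** k-fold CV (default 5) on a seeded shuffle,
fold sizes differing by at most one; per fold, test AUC of held-out
presences against the full background and omission at the training MTSS
threshold.  AUC is the Mann–Whitney probability (ties half).  AICc uses
K = number of nonzero weights and the presence likelihood with raw
normalized to sum 1 over a supplied cell set (the background sample
discretizes the landscape); n ≤ K+1 yields +∞ with a warning so the model
cannot win selection.  The tuning grid ranks by AICc with near-ties
(ΔAICc < 2) resolved by lower mean omission, then higher mean test AUC,
then listing order.

**Thresholds.** MTSS scans the unique predicted values (equivalent to a
dense sweep, verified in tests) counting `score ≥ θ` as suitable, ties to
the smallest θ; P10 is the linearly interpolated 10th percentile of
presence scores.  Binarization uses ≥, so a cell exactly at the threshold
is suitable; the top-habitat cutoff (default 0.9) is a config value.

**Importance.** Permutation importance permutes one predictor across
presence + background rows and records the training-AUC drop (mean over
shuffles), normalized to 100.  Percent contribution is a
path-independent surrogate — Σ |weight|·sd of the predictor's features
over the background, product features split evenly between their two
owners, normalized to 100; the original software's path-dependent
tracking is deliberately not imitated, and the two measures can disagree.
The jackknife refits with only / without each predictor and reports
unpenalized training gains.

## Density estimation

The REM default is the gas-model form `D = (y/t)·π/(v·r·(2+θ))`,
dimensionally consistent with speed in km/day and radius in km.  A
literal variant `D = (y/t)/(v·π·r²·θ)` exists behind
`formula="as_printed"` for auditing published numbers computed that way;
the formula used is recorded on every estimate.  Detections are pooled
across stations — the estimator targets a single area-wide density;
per-station rates remain available in the dataset for diagnostics.

The parametric bootstrap draws `v ~ N(16, 6)` km/day and
`r ~ N(0.020, 0.002)` km (the ±2 m on the detection distance read as a
standard deviation), excludes non-positive draws (expected fraction
Φ(−16/6) + Φ(−10) ≈ 0.0038), recomputes D per draw, and reports both the
bootstrap mean and the plug-in estimate at the prior means — the two
differ because D is convex in v (Jensen), and which one a study calls
"the density" is a reporting choice; the percentile 2.5/97.5 interval
(linear-interpolation quantiles) is the 95% CI.  Coverage of the
simulating density is ≥ 90% over seeded replicates in the acceptance
suite.  Population size over an area is ⌈area × density⌉ ("up to N"),
reported with the unrounded product.

## Association statistics

**Mantel.** r is the Pearson correlation of strictly-lower-triangle
entries; the null jointly permutes rows and columns of the second matrix.
p = (exceedances + 1)/(n_perm + 1), one-tailed upper — the natural tail
for an association question and the one matching upper-quantile
reporting; with 999 permutations p cannot fall below 0.001.  Null upper
quantiles (90/95/97.5/99%) are always reported.  For n ≤ 8 an exact mode
enumerates all n! relabelings.  Unequal species sample sizes are handled
by seeded subsampling of the larger set to the smaller's size; because a
single draw is arbitrary, the default wrapper repeats the draw
(default 100×) and reports the full table of (r, p) so median and spread
can be quoted.  Caveat: the statistic compares distances between
*corresponding* record indices; with independently collected species
records there is no meaningful row correspondence and r hovers near zero
even for strongly co-occurring species — the raster-based statistics are
the robust overlap measures.  No correction for spatial autocorrelation
is attempted beyond these mechanics.

**Raster overlap.** Rasters are aligned to a template by bilinear
interpolation (template cell centers mapped to fractional source
indices); any stencil touching nodata or leaving the source extent
propagates nodata.  Schoener's D normalizes both surfaces to sum 1 over
shared valid cells and returns `1 − ½Σ|p_i − q_i|` — symmetric, in
[0, 1], invariant to positive rescaling.  The correlation suite converts
cells to rows (missing excluded): Pearson runs on all valid rows,
Spearman on a branch that drops rows where every layer is 0 and then
takes a seeded stratified subsample capped at 5,000 rows — strata are a
4×4 partition into equal-area spatial blocks with proportional allocation
(largest-fractional-part remainders), chosen to preserve spatial
representativeness while keeping the subsample reproducible.  A flag can
extend the zero-row filter to the Pearson branch.  Each family of
pairwise p-values is Benjamini–Hochberg adjusted.

## Problem sizes and numerics

Tests and the acceptance script run on 40×40-cell landscapes, hundreds of
presences, ~1,000-cell backgrounds, 10,000-draw bootstraps and 200
replicate recovery studies — sizes at which every stochastic check is
stable across seeds while the whole suite stays fast.  All randomness
flows through `numpy.random.default_rng` seeds; generators are pure
functions of seed and parameters, and fixed seeds reproduce results
bit-identically.  Degenerate inputs (constant distance matrices,
all-zero rasters or bias layers, zero-variance layers, empty score sets,
non-positive effort) raise or warn explicitly rather than propagating
NaNs.

## Known limitations

- Suitability maps and their thresholds are relative to the background
  sample; they are not occupancy probabilities.
- Percent contribution is a surrogate, not the original path-dependent
  definition; compare against permutation importance before interpreting.
- The REM assumes ideal-gas movement (no home ranges, no road/trail bias
  in camera placement) and independent detections.
- The Mantel subsampling design is one documented interpretation of
  comparing unequal point sets; it is not a standard of the literature.
- Raster I/O is single-band ESRI ASCII grid only; CRS handling is a tag
  check, not a reprojection engine.
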