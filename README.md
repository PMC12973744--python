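# wildscape

Spatial predator–prey analysis for terrestrial ecology: from occurrence
records and environmental rasters to habitat-suitability maps, camera-trap
density estimates with bootstrap uncertainty, suitability-weighted
population sizes, and predator–prey spatial-association statistics.

The package is aimed at ecologists studying a large carnivore and its
ungulate prey in a protected area: where is habitat suitable for each
species, how many predators can the best habitat support, and do the
predator's and prey's distributions co-vary in space?  Every stage can be
exercised on synthetic study systems with known ground truth, so each
estimator is testable without any field data.

## What it computes

**Habitat suitability (penalized maxent SDM).**  With presence-only
records and a background sample of landscape cells, the species
distribution over cells is the Gibbs distribution
`q_λ(x) ∝ exp(λ·f(x))` fitted by maximizing the L1-penalized
log-likelihood

```
J(λ) = mean_presence[λ·f] − log(mean_background[exp(λ·f)]) − rm·Σ_j β_j|λ_j|
```

with linear/quadratic/product/hinge feature expansions `f`, per-feature
penalties `β_j` shrinking as `1/√n`, and the regularization multiplier
`rm` tuned together with the feature-class set on an AICc-ranked grid
(ties broken by cross-validated omission rate, then test AUC).
Predictions come in raw, logistic, and cloglog form; maps are binarized
at the maximum-training-sensitivity-plus-specificity (MTSS) or
10th-percentile-presence (P10) threshold.  Supporting steps: iterative
VIF multicollinearity screening (threshold 5 on a 10,000-cell subsample),
distance-to-class predictors, and a kernel-density sampling-bias layer
(σ = 3 km, min–max normalized) for bias-corrected background sampling.

**Density (Random Encounter Model).**  Camera-trap trapping rate `y/t`
converts to density through the ideal-gas encounter model
`D = (y/t)·π / (v·r·(2+θ))` — speed `v` in km/day, detection radius `r`
in km, detection angle `θ` in radians.  A 10,000-draw parametric
bootstrap over `v ~ N(16, 6)` km/day and `r ~ N(20, 2)` m (non-positive
draws excluded) yields a percentile 95% CI.  `population_size` converts a
density and the area with suitability ≥ 0.9 into a supportable headcount.

**Spatial association.**  Mantel tests on per-species Euclidean distance
matrices (999 permutations, upper-tail p, null quantiles reported, exact
enumeration for small n); Schoener's D overlap between suitability
surfaces; pairwise Pearson/Spearman correlations of raster cells with an
all-zero-row filter, seeded stratified subsampling capped at 5,000 rows,
and Benjamini–Hochberg adjustment.

Rasters are carried as plain-text ESRI ASCII grids; occurrences and
camera tables as CSV.

## Worked example

`python examples/04_wolf_density_rem.py` simulates 48 cameras over 100
days at a true density of 1.2 individuals/km² and prints:

```
pooled detections y = 1650, effort t = 4800 days, trapping rate y/t = 0.3438/day
REM point estimate: 1.218 ind/km^2 (truth 1.2)
bootstrap mean density: 1.593 ind/km^2, 95% CI [0.68, 4.07] (44 non-positive draws excluded)
78.95 km^2 of top habitat at 1.2 ind/km^2 supports up to 95 individuals (94.74 unrounded)
```

The point estimate recovers the simulating density from the trapping
rate; the bootstrap mean sits above it because density is inversely
proportional to the speed draw (Jensen's inequality under a wide movement
prior), and the interval is correspondingly right-skewed.  The final line
is the population extrapolation: ⌈78.95 × 1.2⌉ = 95.  The other examples
(`examples/01`–`05`) walk through landscape generation, occurrence
thinning, suitability modelling, and the association statistics.

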