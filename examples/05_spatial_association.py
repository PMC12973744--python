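"""Predator-prey spatial association: Mantel test and raster overlap.

A predator and its preferred prey share habitat preferences, so their
occurrence geometries and predicted distributions should co-vary.  The
Mantel test correlates the species' pairwise-distance matrices (999
permutations); Schoener's D, Pearson and Spearman (with BH-adjusted
p-values) compare the predicted suitability surfaces cell by cell.
"""

import numpy as np

import wildscape as ws

EXTENT = (0.0, 0.0, 4000.0, 4000.0)

stack = ws.generate_predictor_stack(seed=5, extent=EXTENT, cell_size=100.0,
                                    n_layers=3)
truth = ws.ScenarioTruth(
    seed=5, extent=EXTENT,
    species_coefficients={
        "wolf": np.array([1.5, 0.0, 0.0]),      # tracks the same field ...
        "roe_deer": np.array([1.2, 0.3, 0.0]),  # ... as its preferred prey
        "wild_boar": np.array([-1.0, 0.8, 0.0]),  # prefers different ground
    })
occ = ws.generate_occurrences(truth, stack,
                              {"wolf": 280, "roe_deer": 126, "wild_boar": 329})

wolf = occ.subset("wolf")
for prey in ("roe_deer", "wild_boar"):
    draws = ws.mantel_association(wolf, occ.subset(prey), n_perm=999,
                                  n_draws=20, seed=0)
    print(f"Mantel wolf vs {prey}: median r = {draws['r'].median():.4f}, "
          f"median p = {draws['p'].median():.3f} over {len(draws)} subsample draws")
# note: the Mantel statistic compares distances between *corresponding*
# record indices; when the two species' records are sampled independently
# (as here) there is no meaningful row correspondence and r stays near 0
# even for species sharing the same habitat — the raster-based statistics
# below are the robust way to measure distributional overlap

# predicted-distribution overlap
bg = ws.sample_background(stack, 1000, seed=0)
suits = {}
for sp in ("wolf", "roe_deer", "wild_boar"):
    pres = ws.extract_presence_values(occ.subset(sp), stack)
    model = ws.fit_maxent(pres, bg, fc="L", rm=1.0)
    suits[sp] = ws.predict_suitability(model, stack, "cloglog")

report = ws.correlation_suite(suits, max_n=5000, seed=0)
print(report[["pair", "schoener_d", "pearson_r", "pearson_p_adj",
              "spearman_rho", "spearman_p_adj"]]
      .to_string(index=False, float_format="%.4f"))
# high Schoener's D / correlations for the habitat-sharing pair, low for
# the habitat-splitting pair
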