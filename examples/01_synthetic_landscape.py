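"""Generate a synthetic study system: predictors, occurrences, cameras.

Builds a 4 x 4 km landscape of co-registered predictor rasters, samples
species occurrence points whose intensity follows known coefficients, and
simulates a year-long camera-trap deployment from a known true density.
"""

import numpy as np

import wildscape as ws

EXTENT = (0.0, 0.0, 4000.0, 4000.0)

stack = ws.generate_predictor_stack(seed=1, extent=EXTENT, cell_size=100.0,
                                    n_layers=4)
print("predictor layers:", ", ".join(stack))

truth = ws.ScenarioTruth(
    seed=1, true_density=1.2, extent=EXTENT,
    species_coefficients={
        "wolf": np.array([1.5, 0.0, -0.5, 0.0]),
        "roe_deer": np.array([1.0, 0.5, 0.0, 0.0]),
    })
occ = ws.generate_occurrences(truth, stack, {"wolf": 280, "roe_deer": 126})
print("occurrences per species:", occ.species_counts())

cams = ws.simulate_camera_encounters(truth, n_cameras=48, effort_days=100.0)
print(f"cameras: {len(cams.stations)}, pooled detections y = {cams.pooled_y}, "
      f"pooled effort t = {cams.pooled_t:.0f} camera-days")
print(f"trapping rate y/t = {cams.pooled_y / cams.pooled_t:.4f} per day "
      f"(true density {truth.true_density} ind/km^2 drives this rate)")
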