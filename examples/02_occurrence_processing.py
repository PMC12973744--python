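"""Deduplicate and spatially thin multi-source occurrence records.

Duplicates share species, coordinates and date; thinning leaves at most
one record per species per raster cell (earliest date wins), curbing the
influence of locally oversampled areas on the suitability model.
"""

import numpy as np
import pandas as pd

import wildscape as ws
from wildscape.raster import RasterGrid

rng = np.random.default_rng(2)
n = 400
df = pd.DataFrame({
    "species": "wolf",
    "x": rng.uniform(0, 2000, n).round(-1),   # coarse GPS: many shared cells
    "y": rng.uniform(0, 2000, n).round(-1),
    "date": pd.Timestamp("2023-03-01")
            + pd.to_timedelta(rng.integers(0, 420, n), unit="D"),
    "source": rng.choice(["survey", "camera", "roadkill", "citizen"], n),
    "count": 1,
})
# inject exact duplicates (double-reported sightings)
df = pd.concat([df, df.iloc[:25]], ignore_index=True)
occ = ws.OccurrenceSet(df)

dedup = ws.deduplicate(occ)
grid = RasterGrid(np.zeros((20, 20)), (0.0, 0.0), 100.0)
thin = ws.thin_to_grid(dedup, grid)

print(f"raw records:        {len(occ)}")
print(f"after deduplication: {len(dedup)}  (removed {len(occ) - len(dedup)} exact repeats)")
print(f"after thinning:      {len(thin.occurrences)}  "
      f"(one per occupied cell; {len(thin.rejected)} outside the grid)")
print("thinning is idempotent:",
      len(ws.thin_to_grid(thin.occurrences, grid).occurrences)
      == len(thin.occurrences))
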