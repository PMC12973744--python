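"""Occurrence record handling: loading, validation, deduplication, thinning.

Presence-only records arrive from heterogeneous sources (field surveys,
camera traps, roadkill reports, citizen science) in projected coordinates.
Before they feed a suitability model they are deduplicated (same species,
coordinates and date) and spatially thinned so that each raster cell holds
at most one point per species, which limits the influence of locally
oversampled areas.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["OccurrenceSet", "LoadResult", "load_occurrences", "deduplicate",
           "thin_to_grid", "ThinResult"]

REQUIRED_COLUMNS = ("species", "x", "y", "date", "source", "count")


@dataclasses.dataclass
class OccurrenceSet:
    """Validated occurrence records in a projected CRS (metres).

    The record table preserves input order; dedup/thinning always return a
    subsequence of the input.
    """

    records: pd.DataFrame
    crs_tag: str = "EPSG:32633"
    extent: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        if len(self.records) and (self.records["count"] < 1).any():
            raise ValueError("count must be >= 1 for every record")

    def __len__(self) -> int:
        return len(self.records)

    def species_counts(self) -> dict[str, int]:
        return self.records["species"].value_counts().to_dict()

    def subset(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet(self.records[self.records["species"] == species],
                             self.crs_tag, self.extent)

    def coordinates(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.records.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


@dataclasses.dataclass
class LoadResult:
    occurrences: OccurrenceSet
    rejected: pd.DataFrame  # original rows + 'reason' column

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def load_occurrences(path: str | Path, crs_tag: str = "EPSG:32633") -> LoadResult:
    """Parse an occurrence CSV, dropping (and reporting) malformed rows.

    Rows with unparseable coordinates, dates or counts are collected into a
    rejection table with a reason per row rather than raising; a missing
    required column is a schema error and does raise.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    x = pd.to_numeric(raw["x"], errors="coerce")
    y = pd.to_numeric(raw["y"], errors="coerce")
    date = pd.to_datetime(raw["date"], errors="coerce", format="mixed")
    count = pd.to_numeric(raw["count"], errors="coerce")

    reasons = pd.Series("", index=raw.index)
    reasons[~np.isfinite(x) | ~np.isfinite(y)] = "bad coordinates"
    bad_date = date.isna() & (reasons == "")
    reasons[bad_date] = "bad date"
    bad_count = (count.isna() | (count < 1)) & (reasons == "")
    reasons[bad_count] = "bad count"
    blank_species = (raw["species"].str.strip() == "") & (reasons == "")
    reasons[blank_species] = "blank species"

    bad = reasons != ""
    rejected = raw[bad].copy()
    rejected["reason"] = reasons[bad]

    kept = pd.DataFrame({
        "species": raw["species"][~bad],
        "x": x[~bad], "y": y[~bad],
        "date": date[~bad],
        "source": raw["source"][~bad],
        "count": count[~bad].astype(int),
    })
    return LoadResult(OccurrenceSet(kept, crs_tag=crs_tag), rejected)


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop repeat observations: same species, coordinates *and* date.

    The same location observed on different dates is two legitimate
    records.  The first record in input order is kept.
    """
    df = occ.records
    if not len(df):
        return OccurrenceSet(df.copy(), occ.crs_tag, occ.extent)
    kept = df.drop_duplicates(subset=["species", "x", "y", "date"], keep="first")
    return OccurrenceSet(kept, occ.crs_tag, occ.extent)


@dataclasses.dataclass
class ThinResult:
    occurrences: OccurrenceSet
    rejected: pd.DataFrame  # points outside the grid, with 'reason'


def thin_to_grid(occ: OccurrenceSet, grid: RasterGrid) -> ThinResult:
    """Spatially thin so each grid cell holds at most one record per species.

    Within a (species, cell) group the record with the earliest date wins;
    remaining ties go to the first record in input order.  Points outside
    the grid are reported in the rejection table, not silently dropped.
    """
    df = occ.records
    if not len(df):
        return ThinResult(OccurrenceSet(df.copy(), occ.crs_tag, occ.extent),
                          df.assign(reason=pd.Series(dtype=str)))
    row, col = grid.cell_index(df["x"].to_numpy(float), df["y"].to_numpy(float))
    nrows, ncols = grid.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)

    rejected = df[~inside].copy()
    rejected["reason"] = "outside grid"

    kept = df[inside].copy()
    kept["_cell"] = row[inside] * ncols + col[inside]
    kept["_order"] = np.arange(len(kept))
    kept = kept.sort_values(["date", "_order"], kind="stable")
    kept = kept.drop_duplicates(subset=["species", "_cell"], keep="first")
    kept = kept.sort_values("_order").drop(columns=["_cell", "_order"])
    return ThinResult(OccurrenceSet(kept, occ.crs_tag, occ.extent), rejected)
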