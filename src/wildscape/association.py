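"""Predator-prey spatial association statistics.

Two complementary views of spatial association:

* from occurrence points — the Mantel test correlates the pairwise
  Euclidean distance matrices of two species; significance comes from
  joint row/column permutations of one matrix, and the upper quantiles of
  the null distribution are reported alongside r and p;
* from predicted suitability rasters — Schoener's D niche-overlap
  statistic on sum-normalized surfaces, plus pairwise Pearson and
  Spearman correlations of cell values with Benjamini-Hochberg adjusted
  p-values.

Unequal species sample sizes are reconciled for the Mantel test by seeded
subsampling of the larger set, optionally repeated with the median
statistic reported.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .occurrences import OccurrenceSet
from .raster import RasterGrid

__all__ = [
    "DistanceMatrix", "MantelResult", "euclidean_distance_matrix",
    "pair_species_points", "mantel_test", "mantel_association",
    "align_rasters", "schoener_overlap", "correlation_suite",
    "stratified_cell_sample", "bh_adjust",
]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]

NULL_QUANTILES = (90.0, 95.0, 97.5, 99.0)


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with point labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate point ids")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in condensed (pdist) order."""
        return squareform(self.values, checks=False)


def euclidean_distance_matrix(points: np.ndarray,
                              labels: list[str] | None = None) -> DistanceMatrix:
    """All-pairs Euclidean distances of projected (x, y) coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    if labels is None:
        labels = [f"p{i}" for i in range(len(pts))]
    return DistanceMatrix(labels, squareform(pdist(pts)))


def pair_species_points(occA: OccurrenceSet, occB: OccurrenceSet,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equal-size coordinate lists from two species' occurrence sets.

    The larger set is subsampled without replacement (seeded) down to the
    size of the smaller; selected rows keep their input order so the
    result is deterministic.
    """
    a = occA.coordinates()
    b = occB.coordinates()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both occurrence sets must be nonempty")
    rng = np.random.default_rng(seed)
    n = min(len(a), len(b))
    if len(a) > n:
        a = a[np.sort(rng.choice(len(a), size=n, replace=False))]
    if len(b) > n:
        b = b[np.sort(rng.choice(len(b), size=n, replace=False))]
    return a, b


@dataclasses.dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    null_quantiles: dict[float, float]
    seed: int | None
    tail: str = "upper"


def _mantel_r(da: np.ndarray, db: np.ndarray) -> float:
    sa, sb = da.std(), db.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    return float(np.corrcoef(da, db)[0, 1])


def mantel_test(mA: DistanceMatrix, mB: DistanceMatrix,
                n_perm: int = 999, seed: int = 0,
                method: str = "permutation") -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries.
    The null is generated by jointly permuting rows and columns of the
    second matrix; the one-tailed upper p-value is
    ``(#{null r >= observed} + 1) / (n_perm + 1)``, never below
    ``1/(n_perm+1)``.  ``method="exact"`` enumerates all n! relabelings
    (n <= 8) and reports ``#{null r >= observed} / n!`` — the identity
    permutation is part of the enumeration.  Upper null quantiles at
    90/95/97.5/99% are reported either way.
    """
    if len(mA) != len(mB):
        raise ValueError("matrices must have equal dimensions")
    n = len(mA)
    if n < 3:
        raise ValueError("need at least 3 points")
    da = mA.condensed()
    B = mB.values
    r_obs = _mantel_r(da, mB.condensed())

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        null = np.array([
            _mantel_r(da, squareform(B[np.ix_(p, p)], checks=False))
            for p in itertools.permutations(range(n))
        ])
        p_val = float(np.mean(null >= r_obs - 1e-12))
        n_used = math.factorial(n)
        used_seed = None
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            null[i] = _mantel_r(da, squareform(B[np.ix_(perm, perm)], checks=False))
        p_val = (np.count_nonzero(null >= r_obs - 1e-12) + 1) / (n_perm + 1)
        n_used = n_perm
        used_seed = seed
    else:
        raise ValueError(f"unknown method {method!r}")

    quant = {q: float(np.percentile(null, q)) for q in NULL_QUANTILES}
    return MantelResult(r=r_obs, p=float(p_val), n_perm=n_used,
                        null_quantiles=quant, seed=used_seed)


def mantel_association(occA: OccurrenceSet, occB: OccurrenceSet,
                       n_perm: int = 999, n_draws: int = 100,
                       seed: int = 0) -> pd.DataFrame:
    """Mantel association between two species with unequal sample sizes.

    The larger set is subsampled to equal size; with ``n_draws > 1`` the
    subsampling is repeated and each draw's (r, p) recorded so the median
    and spread can be reported rather than a single arbitrary draw.
    ``n_draws=1`` mimics a single-subsample analysis.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_draws):
        s = int(rng.integers(0, 2**31 - 1))
        a, b = pair_species_points(occA, occB, seed=s)
        res = mantel_test(euclidean_distance_matrix(a),
                          euclidean_distance_matrix(b),
                          n_perm=n_perm, seed=s)
        rows.append({"draw": d, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- rasters
def align_rasters(rasters: list[RasterGrid],
                  template: RasterGrid) -> list[RasterGrid]:
    """Resample rasters onto a template grid with bilinear interpolation.

    Template cell centers are mapped into each source's fractional index
    space; values are bilinearly interpolated, and any target cell whose
    interpolation stencil touches a nodata or out-of-extent source cell is
    nodata in the output.  Disjoint extents are a geometry error.
    """
    tx, ty = template.cell_centers()
    out = []
    for src in rasters:
        xmin, ymin, xmax, ymax = src.extent
        if (tx.min() > xmax or tx.max() < xmin or
                ty.min() > ymax or ty.max() < ymin):
            raise ValueError("source raster extent is disjoint from template")
        nrows, _ = src.shape
        # fractional (row, col) of template centers in the source grid
        col = (tx - xmin) / src.cell_size - 0.5
        row = nrows - (ty - ymin) / src.cell_size - 0.5
        vals = src.values
        bad = ~np.isfinite(vals)
        filled = np.where(bad, 0.0, vals)
        interp = ndimage.map_coordinates(filled, [row, col], order=1,
                                         mode="constant", cval=np.nan)
        badness = ndimage.map_coordinates(bad.astype(float), [row, col],
                                          order=1, mode="constant", cval=1.0)
        interp[badness > 1e-9] = np.nan
        out.append(template.like(interp))
    return out


def schoener_overlap(suitA: RasterGrid, suitB: RasterGrid) -> float:
    """Schoener's D between two nonnegative suitability surfaces.

    Both surfaces are normalized to sum 1 over the shared valid cells;
    ``D = 1 - 0.5 * sum |p_i - q_i|`` lies in [0, 1], with 1 for identical
    and 0 for disjoint distributions.  Symmetric and invariant to positive
    rescaling of either raster.
    """
    if not suitA.same_grid(suitB):
        raise ValueError("rasters must be aligned on the same grid")
    a = suitA.values.ravel()
    b = suitB.values.ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if (a < 0).any() or (b < 0).any():
        raise ValueError("suitability values must be nonnegative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero raster: overlap undefined")
    p = a / a.sum()
    q = b / b.sum()
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def stratified_cell_sample(rows: pd.DataFrame, row_idx: np.ndarray,
                           template: RasterGrid, max_n: int,
                           seed: int, n_blocks: int = 4) -> pd.DataFrame:
    """Seeded stratified subsample of cell rows, capped at ``max_n``.

    Strata are an ``n_blocks x n_blocks`` partition of the grid into
    equal-area spatial blocks; allocation is proportional to stratum size
    with remainders assigned by largest fractional part, preserving
    spatial representativeness of the subsample.
    """
    if len(rows) <= max_n:
        return rows
    nrows_g, ncols_g = template.shape
    r = row_idx // ncols_g
    c = row_idx % ncols_g
    stratum = ((r * n_blocks) // nrows_g) * n_blocks + (c * n_blocks) // ncols_g
    rng = np.random.default_rng(seed)
    counts = pd.Series(stratum).value_counts().sort_index()
    quota_f = counts / counts.sum() * max_n
    quota = np.floor(quota_f).astype(int)
    remainder = max_n - quota.sum()
    if remainder > 0:
        frac_order = (quota_f - quota).sort_values(ascending=False).index
        for s in frac_order[:remainder]:
            quota[s] += 1
    take: list[np.ndarray] = []
    pos = np.arange(len(rows))
    for s, q in quota.items():
        members = pos[stratum == s]
        if q >= len(members):
            take.append(members)
        else:
            take.append(np.sort(rng.choice(members, size=q, replace=False)))
    sel = np.sort(np.concatenate(take))
    return rows.iloc[sel]


def correlation_suite(stack: dict[str, RasterGrid], max_n: int = 5_000,
                      seed: int = 0, drop_all_zero: bool = True,
                      all_zero_filter_pearson: bool = False) -> pd.DataFrame:
    """Pairwise overlap report for aligned suitability rasters.

    Cells become observation rows (missing values excluded).  Pearson runs
    on the full valid set; Spearman on a filtered branch where rows with
    all-zero values are dropped (a spatial-autocorrelation mitigation) and
    a seeded stratified subsample caps the rows at ``max_n`` (strata: 4x4
    spatial blocks, proportional allocation).  Each correlation family's
    p-values are Benjamini-Hochberg adjusted.  Schoener's D per pair is
    included.  Zero-variance layers yield NaN correlations with a warning.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers")
    names = list(stack)
    template = stack[names[0]]
    for g in stack.values():
        if not g.same_grid(template):
            raise ValueError("stack layers are not aligned")
    flat = pd.DataFrame({n: stack[n].values.ravel() for n in names})
    valid = np.isfinite(flat.to_numpy()).all(axis=1)
    rows = flat[valid].reset_index(drop=True)
    row_idx = np.flatnonzero(valid)

    def _branch(df: pd.DataFrame, idx: np.ndarray, filter_zero: bool) -> tuple[pd.DataFrame, np.ndarray]:
        if filter_zero:
            keep = ~(df.to_numpy() == 0).all(axis=1)
            df = df[keep].reset_index(drop=True)
            idx = idx[keep]
        sub = stratified_cell_sample(df, idx, template, max_n, seed)
        return sub, idx

    pearson_rows, _ = _branch(rows, row_idx, all_zero_filter_pearson) \
        if all_zero_filter_pearson else (rows, row_idx)
    spearman_rows, _ = _branch(rows, row_idx, drop_all_zero)

    recs = []
    for a, b in itertools.combinations(names, 2):
        rec: dict[str, object] = {"pair": f"{a}-{b}", "layer_a": a, "layer_b": b}
        try:
            rec["schoener_d"] = schoener_overlap(stack[a], stack[b])
        except ValueError:
            rec["schoener_d"] = np.nan
        xa, xb = pearson_rows[a].to_numpy(), pearson_rows[b].to_numpy()
        if xa.std() == 0 or xb.std() == 0:
            warnings.warn(f"zero-variance layer in pair {a}-{b}")
            rec["pearson_r"], rec["pearson_p"] = np.nan, np.nan
        else:
            r, p = stats.pearsonr(xa, xb)
            rec["pearson_r"], rec["pearson_p"] = float(r), float(p)
        sa, sb = spearman_rows[a].to_numpy(), spearman_rows[b].to_numpy()
        if sa.std() == 0 or sb.std() == 0:
            rec["spearman_rho"], rec["spearman_p"] = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(sa, sb)
            rec["spearman_rho"], rec["spearman_p"] = float(rho), float(p)
        recs.append(rec)
    report = pd.DataFrame(recs)
    for col in ("pearson_p", "spearman_p"):
        raw = report[col].to_numpy(float)
        ok = np.isfinite(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(raw[ok])
        report[col.replace("_p", "_p_adj")] = adj
    report.attrs["sampling"] = {"max_n": max_n, "seed": seed,
                                "strata": "4x4 equal-area spatial blocks"}
    return report
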