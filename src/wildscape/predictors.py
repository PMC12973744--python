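"""Predictor-stack construction and screening.

Covers the standard steps between raw environmental layers and a
suitability model: distance-to-class surfaces from a categorical
land-cover map, terrain derivatives from a DEM, multicollinearity
screening by iterative VIF removal, pairwise predictor correlations, and
a kernel-density sampling-bias layer built from the occurrence records
themselves.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import RasterGrid

__all__ = ["distance_to_class", "vif_filter", "VifReport",
           "pairwise_predictor_correlation", "kde_bias_layer",
           "slope_aspect", "extract_contours", "stack_subsample"]


def distance_to_class(landcover: RasterGrid, class_id: int) -> RasterGrid:
    """Euclidean distance (metres, center-to-center) to the nearest cell of
    a land-cover class.  Cells of the class itself hold 0.

    An integer-labelled raster is required; a class absent from the map
    yields an all-nodata output with a warning rather than an error.
    """
    vals = landcover.values
    finite = np.isfinite(vals)
    if finite.any() and not np.allclose(vals[finite], np.round(vals[finite])):
        raise TypeError("landcover raster must hold integer class labels")
    inside = finite & (vals == class_id)
    if not inside.any():
        warnings.warn(f"class {class_id} not present in landcover raster; "
                      "returning all-nodata distances")
        return landcover.like(np.full(landcover.shape, np.nan))
    dist = ndimage.distance_transform_edt(~inside) * landcover.cell_size
    dist = np.where(finite, dist, np.nan)
    return landcover.like(dist)


def stack_subsample(stack: dict[str, RasterGrid], size: int,
                    seed: int) -> pd.DataFrame:
    """Seeded random subsample of complete (no-missing) cells from a stack.

    Returns a table with one column per layer; used by both the VIF filter
    and the predictor correlation so they see the same cells.
    """
    names = list(stack)
    vals = np.stack([stack[n].values.ravel() for n in names], axis=1)
    complete = np.isfinite(vals).all(axis=1)
    vals = vals[complete]
    if len(vals) == 0:
        raise ValueError("no complete cells in the stack")
    rng = np.random.default_rng(seed)
    if size < len(vals):
        idx = rng.choice(len(vals), size=size, replace=False)
        vals = vals[idx]
    return pd.DataFrame(vals, columns=names)


def _vif_one(design: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) of OLS of column j on the others + intercept."""
    y = design[:, j]
    others = np.delete(design, j, axis=1)
    X = sm.add_constant(others, has_constant="add")
    res = sm.OLS(y, X).fit()
    r2 = min(res.rsquared, 1.0)
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


@dataclasses.dataclass
class VifReport:
    iterations: list[dict[str, float]]   # per-iteration VIF of retained layers
    kept: list[str]
    dropped: list[tuple[str, int]]       # (name, iteration dropped)
    threshold: float
    subsample_size: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it, vifs in enumerate(self.iterations, start=1):
            for name, v in vifs.items():
                rows.append({"iteration": it, "variable": name, "vif": v})
        return pd.DataFrame(rows)


def vif_filter(stack: dict[str, RasterGrid], threshold: float = 5.0,
               subsample_size: int = 10_000, seed: int = 0,
               subsample: pd.DataFrame | None = None) -> VifReport:
    """Iterative worst-first multicollinearity screening.

    On a random subsample of complete cells, compute every retained
    layer's variance inflation factor; while the maximum exceeds the
    threshold, drop the offending layer and recompute.  A perfectly
    collinear layer gets VIF = +inf and is removed first.  Every iteration
    is recorded so the removal path is auditable.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers")
    if subsample is None:
        subsample = stack_subsample(stack, subsample_size, seed)
    names = list(subsample.columns)
    data = subsample.to_numpy(float)

    iterations: list[dict[str, float]] = []
    dropped: list[tuple[str, int]] = []
    active = list(range(len(names)))
    it = 0
    while len(active) >= 2:
        it += 1
        design = data[:, active]
        vifs = {names[a]: _vif_one(design, k) for k, a in enumerate(active)}
        iterations.append(vifs)
        worst = max(vifs, key=lambda n: vifs[n])
        if vifs[worst] <= threshold:
            break
        dropped.append((worst, it))
        active.remove(names.index(worst))
    kept = [names[a] for a in active]
    return VifReport(iterations, kept, dropped, threshold,
                     len(subsample), seed)


def pairwise_predictor_correlation(stack: dict[str, RasterGrid],
                                   subsample: pd.DataFrame | None = None,
                                   subsample_size: int = 10_000,
                                   seed: int = 0) -> pd.DataFrame:
    """Pearson correlation matrix of the stack layers over a cell subsample.

    Zero-variance layers produce undefined correlations, reported as NaN
    with a warning.  Symmetric, unit diagonal.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers")
    if subsample is None:
        subsample = stack_subsample(stack, subsample_size, seed)
    data = subsample.to_numpy(float)
    sd = data.std(axis=0)
    if (sd == 0).any():
        flat = [n for n, s in zip(subsample.columns, sd) if s == 0]
        warnings.warn(f"zero-variance layers {flat}: correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=subsample.columns, columns=subsample.columns)


def kde_bias_layer(points: OccurrenceSet, sigma: float,
                   grid: RasterGrid, weights: np.ndarray | None = None) -> RasterGrid:
    """Gaussian kernel density of sampling effort, min-max normalized to [0,1].

    Each record contributes an isotropic Gaussian kernel of bandwidth
    ``sigma`` (metres) weighted by its ``count`` (individuals observed);
    the default bandwidth used downstream is 3 km.  The surface is
    evaluated at cell centers and linearly rescaled so the minimum is 0
    and the maximum 1, giving a bias layer for background-point sampling.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if len(points) == 0:
        raise ValueError("need at least one point")
    if weights is None:
        weights = points.records["count"].to_numpy(float)
    weights = np.asarray(weights, dtype=float)
    if not (weights > 0).any():
        raise ValueError("all weights are zero")
    coords = points.coordinates()
    gx, gy = grid.cell_centers()
    dens = np.zeros(grid.shape)
    # direct kernel sum; point counts here are hundreds, grids tens of thousands
    for (px, py), w in zip(coords, weights):
        d2 = (gx - px) ** 2 + (gy - py) ** 2
        dens += w * np.exp(-0.5 * d2 / sigma**2)
    dens /= 2 * np.pi * sigma**2
    lo, hi = dens.min(), dens.max()
    if hi == lo:
        raise ValueError("density surface is constant; cannot normalize")
    out = (dens - lo) / (hi - lo)
    out[dens == 0] = 0.0
    return grid.like(out)


def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and aspect (degrees clockwise from north) from a DEM
    using the Horn 3x3 stencil.  Aspect of flat cells is nodata."""
    z = dem.values
    cs = dem.cell_size
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                    f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(dzdx, dzdy))  # 0 = north, clockwise
    aspect = np.mod(aspect, 360.0)
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = np.nan
    return dem.like(slope), dem.like(aspect)


def extract_contours(grid: RasterGrid, levels: list[float]) -> dict[float, list[np.ndarray]]:
    """Optional polyline export of iso-levels (map coordinates, (x, y) rows)."""
    from skimage import measure

    nrows, _ = grid.shape
    x0, y0 = grid.origin
    cs = grid.cell_size
    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        polys = []
        for c in measure.find_contours(grid.values, level):
            x = x0 + (c[:, 1] + 0.5) * cs
            y = y0 + (nrows - c[:, 0] - 0.5) * cs
            polys.append(np.column_stack([x, y]))
        out[level] = polys
    return out
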