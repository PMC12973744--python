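"""Single-band georeferenced raster grids.

:class:`RasterGrid` is the carrier for every gridded surface in the
pipeline: environmental predictors, kernel-density bias layers, predicted
habitat-suitability maps and their binarized forms.  Values live in a 2-D
float array with row 0 at the *top* (north) edge, the convention of the
ESRI ASCII grid format used for on-disk interchange.  Missing cells are
``NaN`` in memory and the ``nodata`` sentinel on disk.

Coordinates are projected metres (the field data convention is UTM); the
CRS is carried as an opaque tag and never reprojected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclasses.dataclass
class RasterGrid:
    """A rectangular single-band grid with an affine (north-up) geotransform.

    Parameters
    ----------
    values:
        2-D float array, row 0 = northernmost row.  NaN marks nodata.
    origin:
        ``(x0, y0)`` coordinates of the lower-left *corner* in metres.
    cell_size:
        Square cell edge length in metres (> 0).
    nodata:
        Sentinel written to disk for NaN cells.
    crs_tag:
        Free-text CRS label, e.g. ``"EPSG:32633"`` (WGS 84 / UTM 33N).
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = _DEFAULT_NODATA
    crs_tag: str = "EPSG:32633"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(x, y)`` of cell-center coordinates, shaped like values."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(ncols) + 0.5) * cs
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * cs
        return np.meshgrid(xs, ys)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) with half-open cells.

        Cells are ``[x0, x0+cs) x [y0, y0+cs)``; points lying exactly on the
        maximum edge of the extent are clamped into the last cell so the full
        closed extent is covered without double assignment.  Points outside
        the extent yield negative or out-of-range indices (caller's problem).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrows, ncols = self.shape
        x0, y0 = self.origin
        cs = self.cell_size
        col = np.floor((x - x0) / cs).astype(int)
        row_from_bottom = np.floor((y - y0) / cs).astype(int)
        xmax = x0 + ncols * cs
        ymax = y0 + nrows * cs
        col = np.where(x == xmax, ncols - 1, col)
        row_from_bottom = np.where(y == ymax, nrows - 1, row_from_bottom)
        row = nrows - 1 - row_from_bottom
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell value lookup at arbitrary coordinates."""
        row, col = self.cell_index(x, y)
        nrows, ncols = self.shape
        ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    # ------------------------------------------------------------------ helpers
    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's geotransform."""
        if np.shape(values) != self.shape:
            raise ValueError("shape mismatch with template grid")
        return RasterGrid(np.asarray(values, dtype=float), self.origin,
                          self.cell_size, self.nodata, self.crs_tag)

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.cell_size - other.cell_size) <= tol
                and abs(self.origin[0] - other.origin[0]) <= tol
                and abs(self.origin[1] - other.origin[1]) <= tol)


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    path = Path(path)
    nrows, ncols = grid.shape
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def _header_lines(lines: Iterator[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for _ in range(6):
        key, val = next(lines).split()
        out[key.lower()] = float(val)
    return out


def read_ascii_grid(path: str | Path, crs_tag: str = "EPSG:32633") -> RasterGrid:
    """Read an ESRI ASCII raster; nodata cells become NaN."""
    path = Path(path)
    with path.open() as fh:
        hdr = _header_lines(iter(fh))
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = hdr.get("nodata_value", _DEFAULT_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    if vals.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError(f"grid shape {vals.shape} disagrees with header in {path}")
    return RasterGrid(vals, (hdr["xllcorner"], hdr["yllcorner"]),
                      hdr["cellsize"], nodata, crs_tag)
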