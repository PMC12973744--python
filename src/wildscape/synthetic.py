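"""Synthetic study systems with known ground truth.

Every downstream stage of the pipeline (occurrence processing, predictor
screening, the suitability model, the encounter-rate density estimator and
the association statistics) is exercised against data generated here, so
each estimator can be checked against the truth that produced its input:

* landscapes: smoothed Gaussian-noise fields (elevation-like) plus
  distance-to-class layers derived from thresholding one field, all
  co-registered;
* occurrences: an inhomogeneous Poisson point process whose log-intensity
  is a linear combination of the predictor layers, sampled by rejection;
* camera detections: Poisson counts under the ideal-gas encounter model
  ``E[y] = t * D * v * r * (2 + theta) / pi`` with density ``D`` in
  individuals/km^2, day-range ``v`` in km/day and detection radius ``r``
  in km.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import RasterGrid, write_ascii_grid

__all__ = [
    "ScenarioTruth",
    "CameraDataset",
    "generate_predictor_stack",
    "generate_occurrences",
    "simulate_camera_encounters",
    "write_scenario",
]

SOURCES = ("survey", "camera", "roadkill", "citizen")

#: per-species occurrence counts of the reference field campaign
FIELD_COUNTS = {"wolf": 280, "wild_boar": 329, "red_deer": 55, "roe_deer": 126}


@dataclasses.dataclass
class ScenarioTruth:
    """Ground-truth parameters of a simulated study system.

    ``true_density`` (ind/km^2), ``true_speed`` (km/day), ``true_radius``
    (km) and ``true_angle`` (radians) parameterize the camera encounter
    model; ``species_coefficients`` maps each species to the vector of
    linear-predictor coefficients that shapes its occurrence intensity
    over the predictor stack.
    """

    seed: int
    true_density: float = 1.2
    true_speed: float = 16.0
    true_radius: float = 0.020
    true_angle: float = 0.77
    species_coefficients: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    extent: tuple[float, float, float, float] = (500_000.0, 4_450_000.0, 510_000.0, 4_460_000.0)
    cell_size: float = 100.0
    date_window: tuple[str, str] = ("2023-03-01", "2024-04-30")

    def __post_init__(self) -> None:
        if self.true_density < 0:
            raise ValueError("true_density must be >= 0")
        if self.true_speed <= 0 or self.true_radius <= 0:
            raise ValueError("true_speed and true_radius must be > 0")
        if not 0 < self.true_angle <= 2 * math.pi:
            raise ValueError("true_angle must lie in (0, 2*pi]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"extent must be well-ordered, got {self.extent}")
        self.species_coefficients = {
            k: np.asarray(v, dtype=float) for k, v in self.species_coefficients.items()
        }


@dataclasses.dataclass
class CameraDataset:
    """Camera-trap deployments with per-station effort and detections."""

    stations: pd.DataFrame  # columns: id, x, y, effort_days, detections

    def __post_init__(self) -> None:
        required = {"id", "x", "y", "effort_days", "detections"}
        missing = required - set(self.stations.columns)
        if missing:
            raise ValueError(f"camera table missing columns: {sorted(missing)}")
        if (self.stations["effort_days"] <= 0).any():
            raise ValueError("every station must have positive effort")
        if (self.stations["detections"] < 0).any():
            raise ValueError("detections must be >= 0")

    @property
    def pooled_y(self) -> int:
        return int(self.stations["detections"].sum())

    @property
    def pooled_t(self) -> float:
        return float(self.stations["effort_days"].sum())

    @classmethod
    def from_csv(cls, path: str | Path) -> "CameraDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.stations.to_csv(path, index=False)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  bandwidth_cells: float = 5.0) -> np.ndarray:
    """Stationary Gaussian random field: smoothed white noise, unit variance."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=bandwidth_cells,
                                    mode="reflect")
    sd = field.std()
    if sd == 0:  # pragma: no cover - degenerate only for tiny grids
        return field
    return (field - field.mean()) / sd


def generate_predictor_stack(seed: int,
                             extent: tuple[float, float, float, float],
                             cell_size: float,
                             n_layers: int,
                             bandwidth_cells: float = 5.0,
                             crs_tag: str = "EPSG:32633") -> dict[str, RasterGrid]:
    """Build ``n_layers`` co-registered continuous predictor rasters.

    Roughly half the layers are smoothed-noise fields (elevation-like
    continuous predictors); the remainder are Euclidean distance surfaces
    to a synthetic land-cover class obtained by thresholding the first
    field at a quantile — the same construction as distance-to-habitat
    predictors derived from a categorical land-cover map.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent}")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    ncols = int(round((xmax - xmin) / cell_size))
    nrows = int(round((ymax - ymin) / cell_size))
    if nrows < 20 or ncols < 20:
        raise ValueError(f"grid must be at least 20x20 cells, got {nrows}x{ncols}")

    rng = np.random.default_rng(seed)
    n_fields = max(1, (n_layers + 1) // 2)
    stack: dict[str, RasterGrid] = {}
    template = RasterGrid(np.zeros((nrows, ncols)), (xmin, ymin), cell_size,
                          crs_tag=crs_tag)
    fields = [_smooth_field(rng, (nrows, ncols), bandwidth_cells)
              for _ in range(n_fields)]
    for i, f in enumerate(fields):
        stack[f"field_{i}"] = template.like(f)

    n_dist = n_layers - n_fields
    # threshold the first field at spread-out quantiles to get source classes
    quantiles = np.linspace(0.25, 0.75, max(n_dist, 1))
    for j in range(n_dist):
        thr = np.quantile(fields[0], quantiles[j])
        inside = fields[0] >= thr
        dist = ndimage.distance_transform_edt(~inside) * cell_size
        stack[f"dist_class_{j}"] = template.like(dist)
    return stack


def _stack_values(stack: dict[str, RasterGrid]) -> np.ndarray:
    grids = list(stack.values())
    for g in grids[1:]:
        if not g.same_grid(grids[0]):
            raise ValueError("stack layers are not co-registered")
    return np.stack([g.values for g in grids], axis=0)


def generate_occurrences(truth: ScenarioTruth,
                         stack: dict[str, RasterGrid],
                         per_species_n: dict[str, int],
                         seed: int | None = None) -> OccurrenceSet:
    """Sample species presence points from an inhomogeneous point process.

    The intensity for species *s* is proportional to
    ``exp(sum_k beta_sk * z_k(x, y))`` where ``z_k`` are the stack layers
    standardized to zero mean and unit variance over the grid.  Points are
    drawn by rejection sampling against the maximum intensity, so the
    requested counts are returned exactly.  Each record carries a date
    uniform over the scenario's collection window, a source label and
    ``count=1``.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    grids = list(stack.values())
    layers = _stack_values(stack)
    mu = layers.reshape(len(grids), -1).mean(axis=1)
    sd = layers.reshape(len(grids), -1).std(axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (layers - mu[:, None, None]) / sd[:, None, None]

    template = grids[0]
    xmin, ymin, xmax, ymax = template.extent
    records = []
    start, end = (np.datetime64(d) for d in truth.date_window)
    n_days = int((end - start) / np.timedelta64(1, "D")) + 1

    for species, n in per_species_n.items():
        if n <= 0:
            raise ValueError(f"requested count for {species} must be > 0")
        beta = truth.species_coefficients.get(species)
        if beta is None:
            raise KeyError(f"no coefficient vector for species {species!r}")
        if beta.shape != (len(grids),):
            raise ValueError(
                f"coefficients for {species} have length {beta.size}, stack has {len(grids)}")
        log_intensity = np.tensordot(beta, z, axes=1)
        cap = np.exp(log_intensity.max())
        if not np.isfinite(cap) or cap <= 0:
            raise ValueError("intensity surface is degenerate; cannot sample")
        xs: list[float] = []
        ys: list[float] = []
        while len(xs) < n:
            m = max(4 * (n - len(xs)), 64)
            px = rng.uniform(xmin, xmax, size=m)
            py = rng.uniform(ymin, ymax, size=m)
            row, col = template.cell_index(px, py)
            lam = np.exp(log_intensity[row, col])
            keep = rng.uniform(0, cap, size=m) < lam
            xs.extend(px[keep][: n - len(xs)])
            ys.extend(py[keep][: n - len(ys)])
        dates = start + rng.integers(0, n_days, size=n).astype("timedelta64[D]")
        sources = rng.choice(SOURCES, size=n)
        records.append(pd.DataFrame({
            "species": species,
            "x": xs, "y": ys,
            "date": pd.to_datetime(dates),
            "source": sources,
            "count": 1,
        }))
    df = pd.concat(records, ignore_index=True)
    return OccurrenceSet(df, crs_tag=template.crs_tag, extent=template.extent)


def encounter_rate(density: float, speed: float, radius: float, angle: float) -> float:
    """Expected detections per camera-day under the gas encounter model."""
    return density * speed * radius * (2.0 + angle) / math.pi


def simulate_camera_encounters(truth: ScenarioTruth,
                               n_cameras: int,
                               effort_days: float | np.ndarray,
                               seed: int | None = None) -> CameraDataset:
    """Simulate per-camera detection counts from the true density.

    Counts are Poisson with mean ``t * D * v * r * (2 + theta) / pi``;
    camera positions are placed uniformly over the scenario extent (they
    are bookkeeping only — the encounter model is spatially implicit).
    """
    if n_cameras < 1:
        raise ValueError("need at least one camera")
    effort = np.broadcast_to(np.asarray(effort_days, dtype=float), (n_cameras,))
    if (effort <= 0).any():
        raise ValueError("effort must be positive for every camera")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    rate = encounter_rate(truth.true_density, truth.true_speed,
                          truth.true_radius, truth.true_angle)
    y = rng.poisson(effort * rate)
    xmin, ymin, xmax, ymax = truth.extent
    df = pd.DataFrame({
        "id": [f"cam_{i:03d}" for i in range(n_cameras)],
        "x": rng.uniform(xmin, xmax, n_cameras),
        "y": rng.uniform(ymin, ymax, n_cameras),
        "effort_days": effort,
        "detections": y,
    })
    return CameraDataset(df)


def write_scenario(outdir: str | Path,
                   truth: ScenarioTruth,
                   stack: dict[str, RasterGrid],
                   occ: OccurrenceSet,
                   cameras: CameraDataset | None = None) -> None:
    """Persist a scenario: predictors as ASCII grids, occurrences and
    cameras as CSV, and the ground truth as a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.items():
        write_ascii_grid(grid, outdir / f"{name}.asc")
    occ.to_csv(outdir / "occurrences.csv")
    if cameras is not None:
        cameras.to_csv(outdir / "cameras.csv")
    truth_dict = dataclasses.asdict(truth)
    truth_dict["species_coefficients"] = {
        k: list(map(float, v)) for k, v in truth.species_coefficients.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth_dict, indent=2))
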