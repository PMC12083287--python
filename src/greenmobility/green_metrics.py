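"""Green-space exposure and inequality metrics on paired population / green rasters.

Two city-level summaries are computed from a :class:`CityRaster`:

* **population-weighted green-space coverage rate** (``exposure``) — the mean
  of per-cell green coverage rates, weighted by each cell's resident
  population.  A coverage rate ``G_i`` is the fraction of green land within a
  walking-access buffer around cell *i*.  Exposure lies in [0, 1]; 1 means
  every resident lives in a fully green neighbourhood.

* **green-space Gini index** (``gini``) — the population-weighted Gini
  inequality index of the per-cell coverage rates.  0 means every resident
  experiences identical coverage; values approaching 1 mean green access is
  concentrated on a small share of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class CityRaster:
    """Co-registered population and green-cover grids for one city.

    ``population`` holds persons per cell (>= 0, at least one positive cell);
    ``green_fraction`` holds the green share of each cell in [0, 1].  Both
    layers must share the same shape; ``cell_size_m`` is the cell edge length
    in metres.
    """

    population: np.ndarray
    green_fraction: np.ndarray
    cell_size_m: float
    city_id: str = "city"

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.green_fraction = np.asarray(self.green_fraction, dtype=float)
        if self.population.shape != self.green_fraction.shape:
            raise ValueError("population and green_fraction must share a shape")
        if self.population.ndim != 2:
            raise ValueError("rasters must be 2-D grids")
        if np.any(self.population < 0):
            raise ValueError("population must be non-negative everywhere")
        if not np.any(self.population > 0):
            raise ValueError("at least one cell must have positive population")
        if np.any(self.green_fraction < 0) or np.any(self.green_fraction > 1):
            raise ValueError("green_fraction must lie in [0, 1]")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")


@dataclass
class GreenMetrics:
    """Per-city green-space summaries (both bounded in [0, 1])."""

    city_id: str
    exposure: float
    gini: float
    buffer_radius_m: float
    greenless: bool = field(default=False)


def _disk_kernel(buffer_radius_m: float, cell_size_m: float) -> np.ndarray:
    """Binary kernel of cells whose centres lie within the buffer radius."""
    r_cells = buffer_radius_m / cell_size_m
    half = int(np.floor(r_cells))
    offsets = np.arange(-half, half + 1)
    di, dj = np.meshgrid(offsets, offsets, indexing="ij")
    return (np.hypot(di, dj) <= r_cells + 1e-9).astype(float)


def green_coverage_rate(raster: CityRaster, buffer_radius_m: float) -> np.ndarray:
    """Per-cell green coverage rate ``G_i``.

    ``G_i`` is the mean ``green_fraction`` over all cells whose centre lies
    within ``buffer_radius_m`` of cell *i*'s centre (cell *i* included).
    Cells outside the raster do not contribute, so edge cells average over
    their truncated neighbourhood.  ``buffer_radius_m = 0`` returns the
    green_fraction layer itself.
    """
    if buffer_radius_m < 0:
        raise ValueError("buffer_radius_m must be non-negative")
    kernel = _disk_kernel(buffer_radius_m, raster.cell_size_m)
    if kernel.size == 1:
        return raster.green_fraction.copy()
    green_sum = ndimage.convolve(raster.green_fraction, kernel, mode="constant", cval=0.0)
    n_in_grid = ndimage.convolve(
        np.ones_like(raster.green_fraction), kernel, mode="constant", cval=0.0
    )
    # clip convolution round-off: the mean of [0,1] values is in [0,1]
    return np.clip(green_sum / n_in_grid, 0.0, 1.0)


def population_weighted_exposure(raster: CityRaster, buffer_radius_m: float = 500.0) -> float:
    """Population-weighted green-space coverage rate, ``sum(P_i G_i) / sum(P_i)``."""
    total = raster.population.sum()
    if total <= 0:
        raise ValueError("total population must be positive (weights undefined)")
    g = green_coverage_rate(raster, buffer_radius_m)
    return float(np.sum(raster.population * g) / total)


def weighted_gini(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Gini index via the Lorenz-curve (sorted, trapezoid) identity.

    Equivalent to ``sum_ij p_i p_j |x_i - x_j| / (2 mu)`` with normalized
    weights ``p``.  Returns 0.0 when the weighted mean is zero.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive total")
    p = weights / wsum
    mu = float(np.dot(p, values))
    if mu == 0.0:
        return 0.0
    order = np.argsort(values, kind="stable")
    p = p[order]
    x = values[order]
    # Lorenz ordinates L_i = cumulative share of weighted value
    cum_val = np.cumsum(p * x) / mu
    prev = np.concatenate(([0.0], cum_val[:-1]))
    # clip summation round-off (exact value is in [0, 1) for non-negative x)
    return float(np.clip(1.0 - np.sum(p * (cum_val + prev)), 0.0, 1.0))


def green_gini(raster: CityRaster, buffer_radius_m: float = 500.0) -> float:
    """Population-weighted Gini index of per-cell green coverage rates.

    0 = every resident sees the same coverage rate; a greenless city
    (weighted mean coverage 0) is returned as 0 rather than NaN so downstream
    models stay finite (flagged via :class:`GreenMetrics`.greenless).
    """
    if raster.population.sum() <= 0:
        raise ValueError("total population must be positive (weights undefined)")
    g = green_coverage_rate(raster, buffer_radius_m)
    return weighted_gini(g, raster.population)


def compute_metrics(raster: CityRaster, buffer_radius_m: float = 500.0) -> GreenMetrics:
    """Both metrics for one raster; flags greenless cities."""
    exposure = population_weighted_exposure(raster, buffer_radius_m)
    gini = green_gini(raster, buffer_radius_m)
    return GreenMetrics(
        city_id=raster.city_id,
        exposure=exposure,
        gini=gini,
        buffer_radius_m=buffer_radius_m,
        greenless=(exposure == 0.0),
    )


def metrics_table(rasters, buffer_radius_m: float = 500.0) -> pd.DataFrame:
    """Tidy per-city metrics table (city_id, exposure, gini, buffer_radius_m)."""
    rows = [compute_metrics(r, buffer_radius_m) for r in rasters]
    return pd.DataFrame(
        {
            "city_id": [m.city_id for m in rows],
            "exposure": [m.exposure for m in rows],
            "gini": [m.gini for m in rows],
            "buffer_radius_m": [m.buffer_radius_m for m in rows],
            "greenless": [m.greenless for m in rows],
        }
    )
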