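"""Synthetic city rasters, covariates and mobility panels with known ground truth.

The generator mirrors the structural assumptions of the downstream analysis:

* **city rasters** — a log-Gaussian population surface (WorldPop-like counts
  per ~100 m cell) paired with a binary green-cover layer obtained by
  thresholding a smooth Gaussian field at a quantile (WorldCover-like).
* **city covariates** — static socioeconomic / demographic / environmental
  attributes (GDP per capita and HDI constant within country), an 8-level
  urban-form category, and monthly time-varying policy stringency (0-100)
  and cumulative infection rate.
* **mobility panel** — daily per-city, per-mode indices built from a monthly
  linear model on the index scale (baseline = 100):

      y_cmt = 100 + x_cmt' beta_mode + b_c + eps_cmt,
      b ~ N(0, sigma_b^2 R),  R_cc' = exp(-d_cc' / rho),  eps iid N(0, sigma_e^2)

  with great-circle distances d, plus iid day-level noise around each monthly
  mean.  Raw emitted values are the index times an arbitrary positive
  per-city scale, with the baseline-date value noise-free, so normalizing a
  series to its baseline date exactly recovers the index scale.

Every random draw is recorded in the returned ground truth so estimators can
be tested against the exact generating values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .distances import haversine_km
from .green_metrics import CityRaster

MODES = ("driving", "walking", "transit")

CITY_TYPES = (
    "high_transit",
    "chequerboard",
    "informal",
    "cul_de_sac",
    "large_block",
    "irregular",
    "intense",
    "motor",
)

#: Default fixed effects per mode, on the index scale (points per unit of the
#: predictor).  Exposure and Gini use the headline estimates of the base
#: driving / walking / transit models; the remaining covariates use modest
#: field-plausible magnitudes on the generator's covariate scales.
DEFAULT_COEF: dict[str, dict[str, float]] = {
    "driving": {
        "exposure": 38.52, "gini": 50.48, "stringency": -0.45,
        "infection_rate": -20.0, "gdp_kusd": 0.05, "hdi": 6.0,
        "nightlight": 0.05, "density_k_km2": -0.4, "pm25": -0.05,
        "median_age": 0.2, "sex_ratio": 0.0,
    },
    "walking": {
        "exposure": 46.82, "gini": 58.88, "stringency": -0.40,
        "infection_rate": -25.0, "gdp_kusd": 0.04, "hdi": 8.0,
        "nightlight": 0.04, "density_k_km2": 0.3, "pm25": -0.04,
        "median_age": 0.1, "sex_ratio": 0.0,
    },
    "transit": {
        "exposure": 75.62, "gini": 162.07, "stringency": -0.55,
        "infection_rate": -40.0, "gdp_kusd": 0.03, "hdi": 10.0,
        "nightlight": 0.06, "density_k_km2": 0.8, "pm25": -0.03,
        "median_age": 0.15, "sex_ratio": 0.0,
    },
}

#: Documented planted-moderation magnitude for power studies: the walking
#: exposure x pandemic-severity interaction at its headline point estimate.
DEFAULT_MODERATION: dict[str, dict[str, float]] = {
    "walking": {"exposure:infection_rate": 148.71},
}

DEFAULT_VARCOMP = {"sigma_b_sq": 25.0, "rho_km": 800.0, "sigma_e_sq": 16.0}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic study.

    ``pop_field`` controls the log-Gaussian population surface (log_mean,
    log_sd, range_cells = Gaussian smoothing radius in cells).  ``green_field``
    controls the thresholded green layer (threshold_quantile = share of cells
    left non-green; quantile_jitter = per-city uniform jitter creating
    between-city variation in green provision; range_cells as above).
    """

    n_cities: int = 50
    grid_shape: tuple[int, int] = (32, 32)
    cell_size_m: float = 100.0
    pop_field: dict = dc_field(
        default_factory=lambda: {"log_mean": 4.0, "log_sd": 1.0, "range_cells": 4.0}
    )
    green_field: dict = dc_field(
        default_factory=lambda: {
            "threshold_quantile": 0.7,
            "range_cells": 5.0,
            "quantile_jitter": 0.15,
        }
    )
    coef_true: dict = dc_field(default_factory=lambda: {m: dict(DEFAULT_COEF[m]) for m in MODES})
    var_components_true: dict = dc_field(default_factory=lambda: dict(DEFAULT_VARCOMP))
    date_span: tuple[str, str] = ("2020-01-13", "2021-12-31")
    baseline_date: str = "2020-01-13"
    day_noise_sd: float = 4.0
    raw_scale_sd: float = 0.3
    buffer_radius_m: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 3:
            raise ValueError(
                "n_cities must be >= 3: hot-spot statistics and the spatial "
                "covariance are degenerate below three sites"
            )
        vc = self.var_components_true
        for key in ("sigma_b_sq", "sigma_e_sq"):
            if vc[key] < 0:
                raise ValueError(f"{key} must be non-negative")
        if vc["rho_km"] <= 0:
            raise ValueError("rho_km must be positive")
        if self.day_noise_sd < 0:
            raise ValueError("day_noise_sd must be non-negative")
        start = pd.Period(pd.Timestamp(self.date_span[0]), freq="M")
        end = pd.Period(pd.Timestamp(self.date_span[1]), freq="M")
        if (end - start).n < 1:
            raise ValueError("date_span must cover at least two calendar months")
        base = pd.Timestamp(self.baseline_date)
        if not (pd.Timestamp(self.date_span[0]) <= base <= pd.Timestamp(self.date_span[1])):
            raise ValueError("baseline_date must lie inside date_span")

    @property
    def months(self) -> pd.PeriodIndex:
        """All calendar months covered by date_span."""
        return pd.period_range(self.date_span[0], self.date_span[1], freq="M")

    @property
    def analysis_months(self) -> pd.PeriodIndex:
        """Months after the baseline month (the regression panel window)."""
        base = pd.Period(pd.Timestamp(self.baseline_date), freq="M")
        return pd.PeriodIndex([m for m in self.months if m > base])


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, stage, index...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def generate_city_sites(config: SyntheticConfig) -> pd.DataFrame:
    """City coordinates with country assignment.

    Cities are scattered over inhabited latitudes and grouped into about
    ceil(n/7) countries by k-means on coordinates, so that national-level
    covariates (GDP, HDI) can be held constant within country.  Singleton
    clusters are merged into the nearest country: a one-city country would
    make its national covariates indistinguishable from that city's other
    attributes (e.g. a unique urban-form dummy) and the design degenerate.
    """
    rng = _rng(config.seed, 0)
    n = config.n_cities
    lon = rng.uniform(-180.0, 180.0, size=n)
    lat = rng.uniform(-60.0, 75.0, size=n)
    n_countries = math.ceil(n / 7)
    km = KMeans(n_clusters=n_countries, n_init=4, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(np.column_stack([lon, lat]))
    if n_countries > 1:
        counts = np.bincount(labels, minlength=n_countries)
        for lab in np.where(counts == 1)[0]:
            i = int(np.where(labels == lab)[0][0])
            others = np.where(labels != lab)[0]
            j = others[np.argmin(np.hypot(lon[others] - lon[i], lat[others] - lat[i]))]
            labels[i] = labels[j]
    return pd.DataFrame(
        {
            "city_id": [f"c{i:03d}" for i in range(n)],
            "lon": lon,
            "lat": lat,
            "country_id": [f"k{j:02d}" for j in labels],
        }
    )


def _smooth_field(shape: tuple[int, int], range_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated standard field: smoothed, re-standardized noise."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=range_cells, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def generate_city_raster(config: SyntheticConfig, city_id: str, seed: int) -> CityRaster:
    """One synthetic population / green-cover raster pair.

    Population is exp(log_mean + log_sd * smooth field) — clustered,
    strictly positive counts.  Green cover is binary: cells where a second
    smooth field exceeds its q-quantile are green, so roughly a (1 - q)
    share of the city is green.  For 0 < q < 1 the effective quantile is
    jittered per city (uniformly within +- quantile_jitter, clipped to
    [0.02, 0.98]) to create between-city variation in green provision; the
    saturated cases q = 0 (all green) and q = 1 (no green) are exact.
    """
    rows, cols = config.grid_shape
    if rows < 4 or cols < 4:
        raise ValueError("grid_shape must be at least 4x4")
    rng = np.random.default_rng(seed)
    pf, gf = config.pop_field, config.green_field

    pop = np.exp(pf["log_mean"] + pf["log_sd"] * _smooth_field((rows, cols), pf["range_cells"], rng))

    q = float(gf["threshold_quantile"])
    if q <= 0.0:
        green = np.ones((rows, cols))
    elif q >= 1.0:
        green = np.zeros((rows, cols))
    else:
        jitter = float(gf.get("quantile_jitter", 0.0))
        q_city = float(np.clip(q + rng.uniform(-jitter, jitter), 0.02, 0.98))
        field = _smooth_field((rows, cols), gf["range_cells"], rng)
        green = (field > np.quantile(field, q_city)).astype(float)
    return CityRaster(population=pop, green_fraction=green, cell_size_m=config.cell_size_m, city_id=city_id)


def generate_city_rasters(config: SyntheticConfig, sites: pd.DataFrame) -> list[CityRaster]:
    """Rasters for every site, with per-city seeds derived from config.seed."""
    seeds = [int(_rng(config.seed, 1, i).integers(2**31)) for i in range(len(sites))]
    return [
        generate_city_raster(config, cid, s)
        for cid, s in zip(sites["city_id"], seeds)
    ]


# global monthly stringency template (Jan 2020 onward), loosely tracing the
# ramp-up / plateau / relaxation shape of lockdown-style policy indices
_STRINGENCY_SHAPE = np.array(
    [5, 25, 70, 82, 75, 65, 55, 50, 48, 52, 58, 60,
     62, 58, 55, 50, 45, 42, 40, 38, 35, 33, 30, 28],
    dtype=float,
)


def generate_covariates(config: SyntheticConfig, sites: pd.DataFrame):
    """Static city attributes plus monthly stringency / cumulative-infection series.

    Returns ``(static, monthly)`` data frames.  GDP per capita (kUSD) and HDI
    are drawn per country and repeated within it; the other static covariates
    vary by city.  Stringency lies in [0, 100]; the cumulative infection rate
    (fraction of population ever infected) is non-decreasing within city.
    """
    if len(sites) == 0:
        raise ValueError("sites table is empty")
    rng = _rng(config.seed, 2)
    n = len(sites)
    countries = sites["country_id"].unique()
    gdp_by_country = {c: float(np.exp(rng.normal(3.0, 0.8))) for c in countries}
    hdi_by_country = {c: float(rng.uniform(0.45, 0.95)) for c in countries}

    static = pd.DataFrame(
        {
            "city_id": sites["city_id"].to_numpy(),
            "country_id": sites["country_id"].to_numpy(),
            "gdp_kusd": sites["country_id"].map(gdp_by_country).to_numpy(),
            "hdi": sites["country_id"].map(hdi_by_country).to_numpy(),
            "nightlight": rng.uniform(5.0, 60.0, n),
            "density_k_km2": np.exp(rng.normal(0.8, 0.6, n)),
            "pm25": np.exp(rng.normal(np.log(25.0), 0.5, n)),
            "median_age": np.clip(rng.normal(35.0, 6.0, n), 18.0, 52.0),
            "sex_ratio": rng.normal(99.0, 3.0, n),
            "city_type": rng.choice(CITY_TYPES, size=n),
        }
    )

    months = config.months
    m_count = len(months)
    shape = _STRINGENCY_SHAPE[:m_count]
    if m_count > len(_STRINGENCY_SHAPE):
        shape = np.concatenate(
            [_STRINGENCY_SHAPE, np.full(m_count - len(_STRINGENCY_SHAPE), _STRINGENCY_SHAPE[-1])]
        )
    rows = []
    for cid in sites["city_id"]:
        mult = rng.uniform(0.6, 1.2)
        stringency = np.clip(mult * shape + rng.normal(0.0, 5.0, m_count), 0.0, 100.0)
        total = rng.uniform(0.02, 0.30)
        incr = rng.gamma(0.8, 1.0, m_count)
        incr[: min(2, m_count)] = 0.0  # recording typically starts a couple of months in
        s = incr.sum()
        infection = np.cumsum(incr / s * total) if s > 0 else np.zeros(m_count)
        for j, m in enumerate(months):
            rows.append((cid, str(m), stringency[j], infection[j]))
    monthly = pd.DataFrame(rows, columns=["city_id", "month", "stringency", "infection_rate"])
    return static, monthly


def covariate_frame(metrics: pd.DataFrame, static: pd.DataFrame, monthly: pd.DataFrame) -> pd.DataFrame:
    """One row per city x month joining green metrics, static and monthly covariates."""
    frame = monthly.merge(static, on="city_id", how="inner")
    frame = frame.merge(metrics[["city_id", "exposure", "gini"]], on="city_id", how="inner")
    return frame


def apply_coefficients(frame: pd.DataFrame, coef: Mapping[str, float]) -> np.ndarray:
    """Linear predictor ``X beta`` for a named coefficient map.

    Interaction keys use ``"a:b"``; both components are mean-centred (over the
    frame) before the product is formed, matching the design-matrix
    convention of the fitted models.  Raises on unknown or non-numeric terms.
    """
    out = np.zeros(len(frame))
    for name, value in coef.items():
        parts = name.split(":")
        for p in parts:
            if p not in frame.columns:
                raise ValueError(f"unknown predictor in coefficient map: {name!r}")
            if not pd.api.types.is_numeric_dtype(frame[p]):
                raise ValueError(f"predictor {p!r} is not numeric; cannot take a single coefficient")
        if len(parts) == 1:
            out += value * frame[parts[0]].to_numpy(dtype=float)
        else:
            prod = np.ones(len(frame))
            for p in parts:
                col = frame[p].to_numpy(dtype=float)
                prod *= col - col.mean()
            out += value * prod
    return out


def draw_spatial_effects(
    lon: np.ndarray,
    lat: np.ndarray,
    sigma_b_sq: float,
    rho_km: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """City random effects b ~ N(0, sigma_b^2 exp(-d/rho)) on great-circle distances."""
    n = len(lon)
    if sigma_b_sq == 0.0:
        return np.zeros(n)
    dist = haversine_km(lon, lat)
    cov = sigma_b_sq * np.exp(-dist / rho_km)
    cov[np.diag_indices_from(cov)] += 1e-10 * sigma_b_sq
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def simulate_mobility_panel(
    sites: pd.DataFrame,
    metrics: pd.DataFrame,
    covariates: tuple[pd.DataFrame, pd.DataFrame],
    config: SyntheticConfig,
    seed: int | None = None,
):
    """Daily raw mobility panel plus full generative ground truth.

    Monthly city means follow the index-scale mixed model described in the
    module docstring; daily records add iid noise around the monthly mean.
    The baseline month (before the analysis window) is flat at index 100,
    and the baseline date itself carries no day noise, so baseline
    normalization recovers the index scale exactly.

    Returns ``(daily, truth)`` where ``daily`` has columns
    (city_id, date, mode, index_value) and ``truth`` records coefficient maps,
    variance components, the drawn spatial effects ``b``, monthly residuals
    ``eps``, per-city scales and the monthly mean surface.
    """
    missing = set(sites["city_id"]) - set(metrics["city_id"])
    if missing:
        raise ValueError(f"green metrics missing for cities: {sorted(missing)}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 3]) if seed is None else int(seed)
    )

    static, monthly_cov = covariates
    frame = covariate_frame(metrics, static, monthly_cov)
    a_months = [str(m) for m in config.analysis_months]
    frame = frame[frame["month"].isin(a_months)].copy()
    frame = frame.sort_values(["city_id", "month"], kind="stable").reset_index(drop=True)

    city_order = sites["city_id"].to_numpy()
    city_pos = {c: i for i, c in enumerate(city_order)}
    vc = config.var_components_true
    base_month = str(pd.Period(pd.Timestamp(config.baseline_date), freq="M"))
    baseline = pd.Timestamp(config.baseline_date)
    dates = pd.date_range(config.date_span[0], config.date_span[1], freq="D")
    date_month = np.array([str(pd.Period(d, freq="M")) for d in dates])

    truth: dict = {
        "coef_true": {m: dict(config.coef_true[m]) for m in config.coef_true},
        "var_components_true": dict(vc),
        "baseline_date": config.baseline_date,
        "day_noise_sd": config.day_noise_sd,
        "b": {},
        "eps": {},
        "scale": {},
        "monthly_mean": {},
    }
    frames = []
    for mode in MODES:
        if mode not in config.coef_true:
            continue
        xb = apply_coefficients(frame, config.coef_true[mode])
        b = draw_spatial_effects(
            sites["lon"].to_numpy(), sites["lat"].to_numpy(), vc["sigma_b_sq"], vc["rho_km"], rng
        )
        eps = rng.normal(0.0, math.sqrt(vc["sigma_e_sq"]), len(frame))
        mu = 100.0 + xb + b[[city_pos[c] for c in frame["city_id"]]] + eps
        mean_lookup = {
            (c, m): v for c, m, v in zip(frame["city_id"], frame["month"], mu)
        }
        scale = np.exp(rng.normal(0.0, config.raw_scale_sd, len(city_order)))
        truth["b"][mode] = dict(zip(city_order, b))
        truth["eps"][mode] = pd.DataFrame(
            {"city_id": frame["city_id"], "month": frame["month"], "eps": eps}
        )
        truth["scale"][mode] = dict(zip(city_order, scale))
        truth["monthly_mean"][mode] = pd.DataFrame(
            {"city_id": frame["city_id"], "month": frame["month"], "mean": mu}
        )

        for ci, cid in enumerate(city_order):
            means = np.where(
                date_month == base_month,
                100.0,
                np.array([mean_lookup.get((cid, m), np.nan) for m in date_month]),
            )
            noise = rng.normal(0.0, config.day_noise_sd, len(dates))
            noise[dates == baseline] = 0.0
            values = (means + noise) * scale[ci]
            frames.append(
                pd.DataFrame(
                    {
                        "city_id": cid,
                        "date": dates.strftime("%Y-%m-%d"),
                        "mode": mode,
                        "index_value": values,
                    }
                )
            )
    daily = pd.concat(frames, ignore_index=True).dropna(subset=["index_value"])
    return daily, truth


def random_raster_ensemble(n_rasters: int, seed: int, max_grid: int = 30):
    """Yield rasters with randomized population/green-field parameters.

    Grid sizes, population log-scale/clustering, green threshold quantile and
    green clustering range are all drawn fresh per raster (including the
    occasional fully green or greenless city), giving a stress ensemble for
    the [0, 1] range invariants of the green metrics.
    """
    rng = np.random.default_rng(seed)
    for i in range(n_rasters):
        u = rng.uniform()
        q = 0.0 if u < 0.03 else (1.0 if u > 0.97 else rng.uniform(0.02, 0.98))
        cfg = SyntheticConfig(
            n_cities=3,
            grid_shape=(int(rng.integers(6, max_grid + 1)), int(rng.integers(6, max_grid + 1))),
            pop_field={
                "log_mean": rng.uniform(1.0, 6.0),
                "log_sd": rng.uniform(0.3, 2.0),
                "range_cells": rng.uniform(1.0, 8.0),
            },
            green_field={
                "threshold_quantile": q,
                "range_cells": rng.uniform(1.0, 8.0),
                "quantile_jitter": 0.0,
            },
            seed=0,
        )
        yield generate_city_raster(cfg, f"r{i:04d}", seed=int(rng.integers(2**31)))


def simulate_dataset(config: SyntheticConfig):
    """End-to-end synthetic study: sites, rasters, metrics, covariates, panel, truth."""
    from .green_metrics import metrics_table

    sites = generate_city_sites(config)
    rasters = generate_city_rasters(config, sites)
    metrics = metrics_table(rasters, config.buffer_radius_m)
    static, monthly = generate_covariates(config, sites)
    daily, truth = simulate_mobility_panel(sites, metrics, (static, monthly), config)
    return {
        "sites": sites,
        "rasters": rasters,
        "metrics": metrics,
        "static": static,
        "monthly_covariates": monthly,
        "daily_panel": daily,
        "truth": truth,
    }
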