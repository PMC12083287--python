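"""Replicate simulation studies: parameter recovery, moderation power, metric ranges.

These are the package's built-in calibration experiments.  Each one simulates
complete studies from the generator at its documented defaults, runs the full
analysis path (normalize -> aggregate -> design -> spatial mixed fit) and
returns tidy results, so that unbiasedness, confidence-interval coverage,
test size and power can be checked against the generative ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .green_metrics import green_gini, population_weighted_exposure
from .spatial_model import ModelSpec, build_design, fit_spatial_mixed
from .synthetic import (
    DEFAULT_COEF,
    DEFAULT_MODERATION,
    MODES,
    SyntheticConfig,
    random_raster_ensemble,
    simulate_dataset,
)
from .trajectories import aggregate_monthly, normalize_to_baseline

#: Continuous base-model terms whose planted values the recovery study checks.
RECOVERY_TERMS = [
    "exposure", "gini", "gdp_kusd", "hdi", "nightlight", "density_k_km2",
    "pm25", "median_age", "sex_ratio", "stringency", "infection_rate",
]


def fit_replicate(seed: int, spec: ModelSpec, coef_true: dict | None = None,
                  var_components: dict | None = None, n_cities: int = 50):
    """Simulate one full study at the given seed and fit one model to it."""
    kwargs = {}
    if coef_true is not None:
        kwargs["coef_true"] = coef_true
    if var_components is not None:
        kwargs["var_components_true"] = var_components
    cfg = SyntheticConfig(n_cities=n_cities, seed=int(seed), **kwargs)
    data = simulate_dataset(cfg)
    monthly = aggregate_monthly(
        normalize_to_baseline(data["daily_panel"], cfg.baseline_date)
    )
    y, X, cids, _ = build_design(
        monthly, data["metrics"], (data["static"], data["monthly_covariates"]), spec
    )
    return fit_spatial_mixed(y, X, cids, data["sites"], estimation=spec.estimation), cfg


def recovery_study(response: str = "walking", n_reps: int = 50, base_seed: int = 1,
                   n_cities: int = 50) -> dict:
    """Repeated-simulation check of the base model for one mode.

    Replicate r uses seed ``base_seed + r`` (r = 0..n_reps-1).  Returns the
    per-replicate estimates and standard errors for every continuous planted
    coefficient, plus the planted truth, ready for bias / coverage summaries.
    """
    if response not in MODES:
        raise ValueError(f"response must be one of {MODES}")
    spec = ModelSpec(response=response)
    est, se = [], []
    for r in range(n_reps):
        fit, cfg = fit_replicate(base_seed + r, spec, n_cities=n_cities)
        est.append(fit.beta[RECOVERY_TERMS])
        se.append(fit.se[RECOVERY_TERMS])
    truth = {t: DEFAULT_COEF[response][t] for t in RECOVERY_TERMS}
    return {
        "estimates": pd.DataFrame(est).reset_index(drop=True),
        "ses": pd.DataFrame(se).reset_index(drop=True),
        "truth": truth,
        "response": response,
    }


def moderation_study(planted: bool, n_reps: int = 50, base_seed: int = 1,
                     response: str = "walking", n_cities: int = 50) -> pd.DataFrame:
    """Size / power study of the moderation (interaction) analysis.

    Fits the pandemic-severity moderation model (both green metrics
    interacted with the cumulative infection rate).  With ``planted=False``
    all interaction coefficients are generated as zero, so rejections at
    alpha estimate the test size; with ``planted=True`` the documented
    default moderation effect is added and rejections of that term estimate
    power.  Returns one row per replicate x interaction term.
    """
    coef = {m: dict(DEFAULT_COEF[m]) for m in MODES}
    if planted:
        for mode, extra in DEFAULT_MODERATION.items():
            coef[mode].update(extra)
    spec = ModelSpec(
        response=response,
        interactions=[("exposure", "infection_rate"), ("gini", "infection_rate")],
    )
    rows = []
    for r in range(n_reps):
        fit, _ = fit_replicate(base_seed + r, spec, coef_true=coef, n_cities=n_cities)
        for term in ("exposure:infection_rate", "gini:infection_rate"):
            rows.append(
                {
                    "rep": r,
                    "term": term,
                    "estimate": fit.beta[term],
                    "se": fit.se[term],
                    "p": fit.p[term],
                    "planted": coef[response].get(term, 0.0),
                }
            )
    return pd.DataFrame(rows)


def metric_extremes(n_rasters: int = 1000, seed: int = 0) -> dict:
    """Extremes of both green metrics over the randomized raster ensemble."""
    exposures, ginis = [], []
    for raster in random_raster_ensemble(n_rasters, seed=seed):
        exposures.append(population_weighted_exposure(raster, 500.0))
        ginis.append(green_gini(raster, 500.0))
    return {
        "max_exposure": float(np.max(exposures)),
        "max_gini": float(np.max(ginis)),
        "min_exposure": float(np.min(exposures)),
        "min_gini": float(np.min(ginis)),
        "n": n_rasters,
    }
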