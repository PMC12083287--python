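"""Gaussian spatial mixed models for monthly mobility panels.

The model for one transportation mode is

    y = X beta + Z b + eps,
    b ~ N(0, sigma_b^2 R(rho)),   R_cc' = exp(-d_cc' / rho),
    eps ~ N(0, sigma_e^2 I),

where rows are city x month observations, Z maps rows to cities, and d is the
great-circle distance (km) between city centroids.  Variance components are
estimated by numerically maximizing the (restricted) log-likelihood with beta
profiled out by generalized least squares; fixed-effect standard errors come
from (X' V^-1 X)^-1.

Because the random structure lives on cities (C of them) while the panel has
n = C x months rows, all likelihood algebra is reduced to C x C blocks via
the Woodbury identity, which keeps a fit to a fraction of a second even for
hundreds of cities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .distances import haversine_km
from .synthetic import covariate_frame

MODES = ("driving", "walking", "transit")

#: Fixed terms of the base (non-moderation) model for every mode.
BASE_TERMS = [
    "exposure", "gini", "gdp_kusd", "hdi", "nightlight", "density_k_km2",
    "pm25", "median_age", "sex_ratio", "city_type", "season",
    "stringency", "infection_rate",
]

_CATEGORICAL_TERMS = {"city_type", "season"}


@dataclass
class ModelSpec:
    """Declarative description of one model fit."""

    response: str
    fixed_terms: list[str] = dc_field(default_factory=lambda: list(BASE_TERMS))
    interactions: list[tuple[str, str]] = dc_field(default_factory=list)
    covariance: str = "exponential"
    estimation: str = "REML"

    def __post_init__(self) -> None:
        if self.response not in MODES:
            raise ValueError(f"response must be one of {MODES}")
        for a, b in self.interactions:
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValueError(f"interaction ({a}, {b}) members must appear in fixed_terms")
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be 'REML' or 'ML'")


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one spatial mixed model."""

    beta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    varcomp: dict
    loglik: float
    n_obs: int
    n_cities: int
    vif: pd.Series
    vif_mean: float
    converged: bool
    estimation: str
    cov_beta: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        """Long coefficient table with significance stars (*p<0.10 **p<0.05 ***p<0.01)."""
        stars = pd.cut(
            self.p, bins=[-1, 0.01, 0.05, 0.10, 2], labels=["***", "**", "*", ""]
        ).astype(str)
        return pd.DataFrame(
            {"term": self.beta.index, "estimate": self.beta.to_numpy(),
             "se": self.se.to_numpy(), "z": self.z.to_numpy(),
             "p": self.p.to_numpy(), "stars": stars.to_numpy()}
        )


def build_design(
    monthly_panel: pd.DataFrame,
    metrics: pd.DataFrame,
    covariates: tuple[pd.DataFrame, pd.DataFrame],
    spec: ModelSpec,
):
    """Response vector, design matrix and city index for one model.

    One row per city x month with complete data (listwise deletion).
    ``city_type`` is dummy-coded against its alphabetically first observed
    level; ``season`` expands to calendar month-of-year dummies against the
    first observed month.  Continuous moderators are mean-centred before the
    interaction product is formed; main-effect columns stay on their raw
    scale.  An intercept column is always included.

    Returns ``(y, X, city_ids, n_dropped)``.
    """
    static, monthly_cov = covariates
    panel = monthly_panel[monthly_panel["mode"] == spec.response]
    if len(panel) == 0:
        raise ValueError(f"no panel rows for mode {spec.response!r}")
    frame = panel.merge(covariate_frame(metrics, static, monthly_cov),
                        on=["city_id", "month"], how="left")
    frame["season"] = frame["month"].str.slice(5, 7)

    needed = [t for t in spec.fixed_terms]
    for t in needed:
        if t not in frame.columns:
            raise ValueError(f"term {t!r} not found in panel/metrics/covariates")
    complete = frame[["index_value"] + needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    frame = frame[complete].reset_index(drop=True)
    if len(frame) == 0:
        raise ValueError("listwise deletion removed every row")

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(frame))}
    for t in spec.fixed_terms:
        if t in _CATEGORICAL_TERMS or not pd.api.types.is_numeric_dtype(frame[t]):
            levels = sorted(frame[t].astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols[f"{t}[{lev}]"] = (frame[t].astype(str) == lev).astype(float).to_numpy()
        else:
            cols[t] = frame[t].to_numpy(dtype=float)
    for a, b in spec.interactions:
        for part in (a, b):
            if part in _CATEGORICAL_TERMS or not pd.api.types.is_numeric_dtype(frame[part]):
                raise ValueError(f"interaction member {part!r} must be continuous")
        ca = frame[a].to_numpy(dtype=float)
        cb = frame[b].to_numpy(dtype=float)
        cols[f"{a}:{b}"] = (ca - ca.mean()) * (cb - cb.mean())

    X = pd.DataFrame(cols)
    y = frame["index_value"].astype(float).rename("index_value")
    return y, X, frame["city_id"].reset_index(drop=True), n_dropped


def vif(X: pd.DataFrame) -> tuple[pd.Series, float]:
    """Variance inflation factors for every non-intercept column of a design.

    VIF_k = 1 / (1 - R_k^2) with R_k^2 from regressing column k on all the
    other columns (intercept included).  Perfectly collinear columns are
    reported as infinity with a warning.
    """
    terms = [c for c in X.columns if c != "Intercept"]
    if len(terms) < 2:
        raise ValueError("VIF needs at least 2 non-intercept predictors")
    M = X[["Intercept"] + terms].to_numpy(dtype=float) if "Intercept" in X.columns else \
        np.column_stack([np.ones(len(X)), X[terms].to_numpy(dtype=float)])
    out = {}
    for j, t in enumerate(terms, start=1):
        target = M[:, j]
        others = np.delete(M, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = np.sum((target - target.mean()) ** 2)
        if tss <= 0:
            out[t] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out)
    if np.isinf(s).any():
        warnings.warn(
            f"perfect collinearity: infinite VIF for {list(s.index[np.isinf(s)])}",
            stacklevel=2,
        )
    finite = s[np.isfinite(s)]
    return s, float(finite.mean()) if len(finite) else float("inf")


_FAMILIES = {
    "exponential": lambda d, rho: np.exp(-d / rho),
    "gaussian": lambda d, rho: np.exp(-((d / rho) ** 2)),
    "spherical": lambda d, rho: np.where(
        d < rho, 1.0 - 1.5 * (d / rho) + 0.5 * (d / rho) ** 3, 0.0
    ),
}


class _ReducedLikelihood:
    """Profiled -2 log-likelihood, reduced to city-level blocks via Woodbury."""

    def __init__(self, y, X, city_codes, dist_km, family):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        self.C = dist_km.shape[0]
        self.dist = dist_km
        self.family = _FAMILIES[family]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtX = np.zeros((self.C, self.p))
        np.add.at(self.ZtX, city_codes, X)
        self.Zty = np.bincount(city_codes, weights=y, minlength=self.C)
        self.counts = np.bincount(city_codes, minlength=self.C).astype(float)
        self._eye = np.eye(self.C)

    def _core(self, sb2, rho, se2):
        """XtVinvX, XtVinvy, ytVinvy and log|V| for given variance components."""
        if sb2 / se2 < 1e-12:
            XtVinvX = self.XtX / se2
            XtVinvy = self.Xty / se2
            ytVinvy = self.yty / se2
            logdetV = self.n * np.log(se2)
            return XtVinvX, XtVinvy, ytVinvy, logdetV
        c = sb2 / se2
        R = self.family(self.dist, rho) + 1e-10 * self._eye
        choR = cho_factor(R, lower=True)
        logdetR = 2.0 * np.sum(np.log(np.diag(choR[0])))
        Rinv = cho_solve(choR, self._eye)
        G = Rinv / c + np.diag(self.counts)
        choG = cho_factor(G, lower=True)
        logdetG = 2.0 * np.sum(np.log(np.diag(choG[0])))
        KZtX = cho_solve(choG, self.ZtX)
        KZty = cho_solve(choG, self.Zty)
        XtVinvX = (self.XtX - self.ZtX.T @ KZtX) / se2
        XtVinvy = (self.Xty - self.ZtX.T @ KZty) / se2
        ytVinvy = (self.yty - self.Zty @ KZty) / se2
        # |V| = se2^n |I + c R Dm|;  |I + c R Dm| = |R| c^C |G|
        logdetV = self.n * np.log(se2) + logdetR + self.C * np.log(c) + logdetG
        return XtVinvX, XtVinvy, ytVinvy, logdetV

    def neg2loglik_at(self, sb2: float, rho: float, se2: float, reml: bool):
        """-2 log (restricted) likelihood at given variance components."""
        try:
            XtVinvX, XtVinvy, ytVinvy, logdetV = self._core(sb2, rho, se2)
            choA = cho_factor(XtVinvX)
            beta = cho_solve(choA, XtVinvy)
        except np.linalg.LinAlgError:
            return 1e12
        quad = ytVinvy - beta @ XtVinvy
        if quad <= 0 or not np.isfinite(quad):
            return 1e12
        out = logdetV + quad + self.n * np.log(2.0 * np.pi)
        if reml:
            out += 2.0 * np.sum(np.log(np.diag(choA[0]))) - self.p * np.log(2.0 * np.pi)
        return float(out)

    def neg2loglik(self, theta, reml: bool):
        th = np.clip(theta, -25.0, 25.0)
        return self.neg2loglik_at(
            np.exp(th[0]), np.exp(np.clip(th[1], -5.0, 12.0)), np.exp(th[2]), reml
        )

    def solution_at(self, sb2, rho, se2):
        XtVinvX, XtVinvy, _, _ = self._core(sb2, rho, se2)
        cov = np.linalg.inv(XtVinvX)
        beta = cov @ XtVinvy
        return beta, cov, {"sigma_b_sq": float(sb2), "rho_km": float(rho), "sigma_e_sq": float(se2)}

    def solution(self, theta):
        th = np.clip(theta, -25.0, 25.0)
        return self.solution_at(
            np.exp(th[0]), np.exp(np.clip(th[1], -5.0, 12.0)), np.exp(th[2])
        )


_VC_NAMES = ("sigma_b_sq", "rho_km", "sigma_e_sq")


def _prepare(y, X, city_ids, sites, covariance):
    if covariance not in _FAMILIES:
        raise ValueError(f"unknown covariance family {covariance!r}")
    cities = pd.unique(city_ids)
    if len(cities) < 3:
        raise ValueError("at least 3 cities are required for the spatial covariance")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient; drop collinear terms")
    site_order = sites.set_index("city_id").loc[list(cities)]
    dist = haversine_km(site_order["lon"].to_numpy(), site_order["lat"].to_numpy())
    code = {c: i for i, c in enumerate(cities)}
    city_codes = np.array([code[c] for c in city_ids])
    return _ReducedLikelihood(y, Xv, city_codes, dist, covariance), Xv, city_codes, dist, cities


def profile_loglik(y, X, city_ids, sites, varcomp: dict, estimation: str = "REML",
                   covariance: str = "exponential") -> float:
    """(Restricted) log-likelihood at given variance components, beta profiled out."""
    prof, _, _, _, _ = _prepare(y, X, city_ids, sites, covariance)
    return -0.5 * prof.neg2loglik_at(
        varcomp["sigma_b_sq"], varcomp["rho_km"], varcomp["sigma_e_sq"],
        reml=(estimation == "REML"),
    )


def fit_spatial_mixed(
    y: pd.Series,
    X: pd.DataFrame,
    city_ids: pd.Series,
    sites: pd.DataFrame,
    estimation: str = "REML",
    covariance: str = "exponential",
    n_starts: int = 3,
    fixed: dict | None = None,
) -> FitResult:
    """Fit the spatial mixed model by numerical (RE)ML.

    beta is profiled out by GLS at each variance-component trial; the
    three components (sigma_b^2, rho, sigma_e^2) are optimized on the log
    scale by Nelder-Mead from ``n_starts`` moment-informed starting points.
    Entries of ``fixed`` (e.g. ``{"sigma_b_sq": 0.0}``) are held at the given
    value while the rest are estimated — useful for limit checks and
    likelihood-ratio comparisons.  Deterministic given data and starts.
    """
    fixed = dict(fixed or {})
    for k in fixed:
        if k not in _VC_NAMES:
            raise ValueError(f"unknown variance component {k!r}")
    prof, Xv, city_codes, dist, cities = _prepare(y, X, city_ids, sites, covariance)
    reml = estimation == "REML"

    # moment-informed starts from OLS residuals
    beta_ols, _, _, _ = np.linalg.lstsq(Xv, np.asarray(y, float), rcond=None)
    resid = np.asarray(y, float) - Xv @ beta_ols
    s2 = max(float(resid @ resid) / max(len(resid) - Xv.shape[1], 1), 1e-8)
    cmean = np.bincount(city_codes, weights=resid) / np.maximum(
        np.bincount(city_codes), 1
    )
    bvar = float(np.var(cmean, ddof=1)) if len(cmean) > 1 else s2 / 2
    wvar = max(s2 - bvar, 0.05 * s2)
    off = dist[np.triu_indices_from(dist, k=1)]
    rho0 = max(float(np.median(off)) / 3.0, 1.0) if len(off) else 100.0
    starts = [
        (max(bvar, 0.05 * s2), rho0, wvar),
        (0.5 * s2, rho0 * 3.0, 0.5 * s2),
        (0.02 * s2, rho0 / 3.0, 0.98 * s2),
    ][: max(1, n_starts)]

    free_idx = [i for i, nm in enumerate(_VC_NAMES) if nm not in fixed]

    def _components(theta_free):
        vals, j = [], 0
        for i, nm in enumerate(_VC_NAMES):
            if nm in fixed:
                vals.append(float(fixed[nm]))
            else:
                lo, hi = (-5.0, 12.0) if i == 1 else (-25.0, 25.0)
                vals.append(float(np.exp(np.clip(theta_free[j], lo, hi))))
                j += 1
        return vals

    if not free_idx:
        vals = _components(np.array([]))
        fun = prof.neg2loglik_at(*vals, reml=reml)
        beta, cov, varcomp = prof.solution_at(*vals)
        success = np.isfinite(fun)
        best_fun = fun
    else:
        best = None
        for s in starts:
            x0 = np.log(np.maximum(np.asarray(s)[free_idx], 1e-12))
            res = optimize.minimize(
                lambda th: prof.neg2loglik_at(*_components(th), reml=reml),
                x0=x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 800},
            )
            if best is None or res.fun < best.fun:
                best = res
        beta, cov, varcomp = prof.solution_at(*_components(best.x))
        success = bool(best.success and np.isfinite(best.fun))
        best_fun = float(best.fun)
    se = np.sqrt(np.diag(cov))
    zscores = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zscores))
    names = list(X.columns)

    try:
        vif_s, vif_mean = vif(X)
    except ValueError:
        vif_s, vif_mean = pd.Series(dtype=float), float("nan")

    return FitResult(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        z=pd.Series(zscores, index=names),
        p=pd.Series(pvals, index=names),
        varcomp=varcomp,
        loglik=-0.5 * best_fun,
        n_obs=len(y),
        n_cities=len(cities),
        vif=vif_s,
        vif_mean=vif_mean,
        converged=bool(success),
        estimation=estimation,
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
    )


#: Moderators of the moderation families, in presentation order.
MODERATORS = ["gdp_kusd", "hdi", "density_k_km2", "stringency", "infection_rate"]


def run_model_suite(
    monthly_panel: pd.DataFrame,
    metrics: pd.DataFrame,
    covariates: tuple[pd.DataFrame, pd.DataFrame],
    sites: pd.DataFrame,
    estimation: str = "REML",
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """The full nine-model analysis.

    Models 1-3: base models for driving / walking / transit.  Model 4:
    exposure x Gini interaction.  Models 5-9: moderation by GDP, HDI,
    population density, policy stringency and pandemic severity — each
    moderator interacted with both green metrics, fitted per mode (suffixes
    a/b/c = driving/walking/transit).  Returns the tidy stacked coefficient
    table and the individual fits.
    """
    specs: dict[str, ModelSpec] = {}
    for i, mode in enumerate(MODES, start=1):
        specs[str(i)] = ModelSpec(response=mode, estimation=estimation)
    for suffix, mode in zip("abc", MODES):
        specs[f"4{suffix}"] = ModelSpec(
            response=mode, interactions=[("exposure", "gini")], estimation=estimation
        )
    for k, moderator in enumerate(MODERATORS, start=5):
        for suffix, mode in zip("abc", MODES):
            specs[f"{k}{suffix}"] = ModelSpec(
                response=mode,
                interactions=[("exposure", moderator), ("gini", moderator)],
                estimation=estimation,
            )

    rows, fits = [], {}
    for model_id, spec in specs.items():
        yv, Xd, cids, _ = build_design(monthly_panel, metrics, covariates, spec)
        fit = fit_spatial_mixed(yv, Xd, cids, sites, estimation=spec.estimation)
        fits[model_id] = fit
        tidy = fit.tidy()
        tidy.insert(0, "model_id", model_id)
        tidy.insert(1, "response", spec.response)
        rows.append(tidy)
    return pd.concat(rows, ignore_index=True), fits
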