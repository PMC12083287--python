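"""Getis-Ord Gi* hot/cold-spot classification of city mobility indices.

The Gi* statistic asks, for each site, whether its neighbourhood (the site
itself plus its spatial neighbours) carries values significantly above or
below the global mean.  Under the normal approximation the standardized
statistic for site i is

    z_i = (sum_j w_ij x_j - Xbar W_i) / (S sqrt[(n S1_i - W_i^2) / (n - 1)])

with W_i = sum_j w_ij, S1_i = sum_j w_ij^2, Xbar the plain mean and
S the population standard deviation of the x's.  Significant positive z
marks a hot spot, significant negative z a cold spot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import haversine_km

Z_THRESHOLDS = {0.90: 1.645, 0.95: 1.960, 0.99: 2.576}


@dataclass
class SpatialWeights:
    """Site-by-site non-negative weights including self-weight (Gi* convention)."""

    ids: list
    w: np.ndarray
    scheme: str
    param: float

    @property
    def n(self) -> int:
        return len(self.ids)


def build_weights(sites: pd.DataFrame, scheme: str = "distance_band", param: float | None = None) -> SpatialWeights:
    """Binary spatial weights over city coordinates with self-weight 1.

    ``distance_band``: w_ij = 1 iff the great-circle distance d_ij <= param
    (km).  When param is None the band defaults to the smallest distance that
    leaves no site neighbourless (the maximum nearest-neighbour distance).
    ``knn``: w_ij = 1 for the k nearest neighbours, symmetrized by union.
    """
    if len(sites) < 3:
        raise ValueError("at least 3 sites are required")
    dist = haversine_km(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    n = len(sites)
    off = dist + np.diag(np.full(n, np.inf))
    if scheme == "distance_band":
        if param is None:
            param = float(off.min(axis=1).max())
        w = (dist <= param).astype(float)
        np.fill_diagonal(w, 1.0)
        if np.any(w.sum(axis=1) < 2):
            lonely = [sites["city_id"].iloc[i] for i in np.where(w.sum(axis=1) < 2)[0]]
            raise ValueError(
                f"band {param} km leaves sites without neighbours: {lonely[:5]}"
            )
    elif scheme == "knn":
        k = int(param) if param is not None else 4
        if k < 1 or k >= n:
            raise ValueError("knn requires 1 <= k < n_sites")
        w = np.zeros((n, n))
        nearest = np.argsort(off, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        w[rows, nearest.ravel()] = 1.0
        w = np.maximum(w, w.T)  # union symmetrization
        np.fill_diagonal(w, 1.0)
        param = float(k)
    else:
        raise ValueError(f"unknown weight scheme: {scheme!r}")
    return SpatialWeights(ids=list(sites["city_id"]), w=w, scheme=scheme, param=float(param))


def getis_ord_gi_star(values, weights: SpatialWeights) -> np.ndarray:
    """Gi* z-score for every site (self included), vectorized.

    Raises on constant values (the global standard deviation is zero) and on
    degenerate neighbourhoods that span the entire sample (e.g. an all-ones
    weight matrix), where the statistic is 0/0.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError("values length must match the number of sites")
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(np.mean(x**2) - xbar**2)
    if s <= 0:
        raise ValueError("values are constant: Gi* is undefined (zero variance)")
    w = weights.w
    wi = w.sum(axis=1)
    s1 = (w**2).sum(axis=1)
    var_term = (n * s1 - wi**2) / (n - 1)
    if np.any(var_term <= 1e-12):
        raise ValueError(
            "degenerate neighbourhood: some site's neighbourhood spans the whole "
            "sample, so Gi* is 0/0 there"
        )
    return (w @ x - xbar * wi) / (s * np.sqrt(var_term))


def classify_spots(z, ids=None) -> pd.DataFrame:
    """Hot/cold classification from Gi* z-scores.

    |z| >= 2.576 / 1.960 / 1.645 map to the 99 / 95 / 90% classes (boundary
    inclusive); the sign separates hot from cold.  p is the two-sided normal
    p-value.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z))
    klass = np.full(len(z), "not_significant", dtype=object)
    for level, thr in sorted(Z_THRESHOLDS.items()):  # ascending so stronger overwrite
        pct = int(round(level * 100))
        klass[(z >= thr)] = f"hot{pct}"
        klass[(z <= -thr)] = f"cold{pct}"
    out = pd.DataFrame({"z": z, "p": p, "klass": klass})
    if ids is not None:
        out.insert(0, "city_id", list(ids))
    return out


def hotspots_over_time(
    monthly_panel: pd.DataFrame,
    sites: pd.DataFrame,
    scheme: str = "distance_band",
    param: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slice-wise Gi* classification for every mode x month of the panel.

    Returns ``(detail, summary)``: per-city class per slice, and hot/cold
    counts per slice (any significance level) for tracking how spatial
    clustering of mobility evolves over the study period.
    """
    missing = set(monthly_panel["city_id"]) - set(sites["city_id"])
    if missing:
        raise ValueError(f"panel cities missing coordinates: {sorted(missing)[:5]}")
    weights = build_weights(sites, scheme, param)
    details, summaries = [], []
    for (mode, month), grp in monthly_panel.groupby(["mode", "month"], sort=True, observed=True):
        grp = grp.set_index("city_id")["index_value"]
        present = [c for c in weights.ids if c in grp.index]
        if len(present) < weights.n:
            # slice must align with the weights; drop slices with missing cities
            raise ValueError(f"slice {mode}/{month} missing cities; cannot align with weights")
        x = grp.reindex(weights.ids).to_numpy()
        res = classify_spots(getis_ord_gi_star(x, weights), ids=weights.ids)
        res.insert(0, "month", month)
        res.insert(0, "mode", mode)
        details.append(res)
        summaries.append(
            {
                "mode": mode,
                "month": month,
                "n_hot": int(res["klass"].str.startswith("hot").sum()),
                "n_cold": int(res["klass"].str.startswith("cold").sum()),
            }
        )
    detail = pd.concat(details, ignore_index=True)
    summary = pd.DataFrame(summaries)
    return detail, summary
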