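"""Baseline normalization, monthly aggregation and turning points of mobility series.

Raw mobility indices are per-city request volumes rescaled so that a
pre-pandemic baseline date reads 100; values above/below 100 mean stronger/
weaker use of the mode than at baseline.  Daily records are noisy, so the
analysis panel aggregates them to calendar months and indexes the months of
the study window 1..K (month 1 = the first analysis month).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def normalize_to_baseline(daily_panel: pd.DataFrame, baseline_date: str) -> pd.DataFrame:
    """Rescale every city x mode series so the baseline date equals exactly 100.

    Each series is multiplied by ``100 / value(baseline_date)``.  Raises if a
    series is missing the baseline date or has a non-positive value there.
    """
    df = daily_panel.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    base = pd.Timestamp(baseline_date).strftime("%Y-%m-%d")
    at_base = df[df["date"] == base].set_index(["city_id", "mode"])["index_value"]
    groups = df.groupby(["city_id", "mode"], sort=False).size()
    missing = set(groups.index) - set(at_base.index)
    if missing:
        raise ValueError(f"baseline date {base} missing for series: {sorted(missing)[:5]}")
    if (at_base <= 0).any():
        bad = at_base[at_base <= 0].index.tolist()
        raise ValueError(f"non-positive baseline value for series: {bad[:5]}")
    factors = 100.0 / at_base
    key = pd.MultiIndex.from_frame(df[["city_id", "mode"]])
    df["index_value"] = df["index_value"].to_numpy() * factors.reindex(key).to_numpy()
    return df


def aggregate_monthly(
    daily_panel: pd.DataFrame,
    start: str = "2020-02",
    end: str = "2021-12",
    statistic: str = "mean",
) -> pd.DataFrame:
    """Collapse daily records to the monthly analysis panel.

    The monthly value is the arithmetic mean (or median, via ``statistic``)
    of that city x mode's daily values within the calendar month.  Records
    outside [start, end] are excluded and month_index runs 1..K from
    ``start``.  City x mode x month cells with no daily records are simply
    absent (and logged); no imputation is attempted.
    """
    if len(daily_panel) == 0:
        raise ValueError("daily panel is empty")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    df = daily_panel.copy()
    df["month"] = pd.PeriodIndex(pd.to_datetime(df["date"]), freq="M")
    p_start, p_end = pd.Period(start, freq="M"), pd.Period(end, freq="M")
    df = df[(df["month"] >= p_start) & (df["month"] <= p_end)]
    agg = (
        df.groupby(["city_id", "mode", "month"], sort=True, observed=True)["index_value"]
        .agg(statistic)
        .reset_index()
    )
    n_expected = df.groupby(["city_id", "mode"], observed=True).ngroups * ((p_end - p_start).n + 1)
    if len(agg) < n_expected:
        logger.info("monthly aggregation: %d of %d city-mode-month cells populated",
                    len(agg), n_expected)
    agg["month_index"] = agg["month"].map(lambda m: (m - p_start).n + 1)
    agg["month"] = agg["month"].astype(str)
    return agg[["city_id", "mode", "month", "month_index", "index_value"]]


def mean_trajectory(monthly_panel: pd.DataFrame, mode: str) -> pd.Series:
    """Across-city mean monthly index for one mode, indexed by month_index."""
    sub = monthly_panel[monthly_panel["mode"] == mode]
    if len(sub) == 0:
        raise ValueError(f"no records for mode {mode!r}")
    return sub.groupby("month_index")["index_value"].mean().sort_index()


def find_turning_points(series) -> list[int]:
    """Positions where a trajectory switches from falling to rising.

    Returns every interior position t with value(t) < value(t-1) and
    value(t) < value(t+1) — a strict local minimum.  Plateau minima (ties)
    are not reported: the definition requires a strict slope change on both
    sides.  Positions are 0-based into the input sequence.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be one-dimensional with length >= 3")
    interior = np.arange(1, len(x) - 1)
    mask = (x[interior] < x[interior - 1]) & (x[interior] < x[interior + 1])
    return [int(t) for t in interior[mask]]
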