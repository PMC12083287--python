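"""End-to-end orchestration: simulate -> metrics -> trajectories -> hotspots -> models.

All artifacts are plain files (CSV / JSON / NPZ) so a run is fully inspectable;
a manifest records a content hash of every output, making reruns with the same
configuration verifiable byte-for-byte at the array level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hotspot, spatial_model, trajectories
from .green_metrics import CityRaster
from .synthetic import SyntheticConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration (embeds the synthetic ground truth)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    hotspot_scheme: str = "distance_band"
    hotspot_param: float | None = None
    estimation: str = "REML"
    window: tuple[str, str] = ("2020-02", "2021-12")

    @property
    def seed(self) -> int:
        return self.synthetic.seed

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        if "grid_shape" in syn:
            syn["grid_shape"] = tuple(syn["grid_shape"])
        if "date_span" in syn:
            syn["date_span"] = tuple(syn["date_span"])
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(synthetic=SyntheticConfig(**syn), **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash_bytes(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()


def _hash_file(path: Path) -> str:
    """Content hash; NPZ archives are hashed over their arrays (zip headers
    carry timestamps, so raw bytes would not be rerun-stable)."""
    if path.suffix == ".npz":
        h = hashlib.sha256()
        with np.load(path) as z:
            for name in sorted(z.files):
                h.update(name.encode())
                h.update(np.ascontiguousarray(z[name]).tobytes())
        return h.hexdigest()
    return _hash_bytes(path.read_bytes())


def save_raster(path, raster: CityRaster) -> None:
    """2-layer NPZ (population, green_fraction) with a JSON sidecar for metadata."""
    path = Path(path)
    np.savez(path, population=raster.population, green_fraction=raster.green_fraction)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"city_id": raster.city_id, "cell_size_m": raster.cell_size_m})
    )


def load_raster(path) -> CityRaster:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        return CityRaster(
            population=z["population"],
            green_fraction=z["green_fraction"],
            cell_size_m=meta["cell_size_m"],
            city_id=meta["city_id"],
        )


def write_covariates(path, static: pd.DataFrame, monthly: pd.DataFrame) -> None:
    """Long-format covariate CSV: (city_id, month, name, value); static rows
    carry an empty month."""
    rows = []
    for _, r in static.iterrows():
        for c in static.columns:
            if c == "city_id":
                continue
            rows.append((r["city_id"], "", c, r[c]))
    for _, r in monthly.iterrows():
        for c in ("stringency", "infection_rate"):
            rows.append((r["city_id"], r["month"], c, r[c]))
    pd.DataFrame(rows, columns=["city_id", "month", "name", "value"]).to_csv(path, index=False)


def read_covariates(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    long = pd.read_csv(path, keep_default_na=False, dtype={"month": str})
    stat = long[long["month"] == ""].pivot(index="city_id", columns="name", values="value")
    numeric = [c for c in stat.columns if c not in ("country_id", "city_type")]
    stat[numeric] = stat[numeric].astype(float)
    stat = stat.reset_index().rename_axis(None, axis=1)
    mon = (
        long[long["month"] != ""]
        .pivot(index=["city_id", "month"], columns="name", values="value")
        .astype(float)
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return stat, mon


def simulate_artifacts(config: RunConfig, out_dir) -> dict:
    """Generate and write every synthetic artifact plus ground truth and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    data = simulate_dataset(config.synthetic)

    data["sites"].to_csv(out / "sites.csv", index=False)
    data["metrics"].to_csv(out / "metrics.csv", index=False)
    data["daily_panel"].to_csv(out / "daily_panel.csv", index=False)
    write_covariates(out / "covariates.csv", data["static"], data["monthly_covariates"])
    raster_dir = out / "rasters"
    raster_dir.mkdir(exist_ok=True)
    for raster in data["rasters"]:
        save_raster(raster_dir / f"{raster.city_id}.npz", raster)

    truth = data["truth"]
    truth_json = {
        "coef_true": truth["coef_true"],
        "var_components_true": truth["var_components_true"],
        "baseline_date": truth["baseline_date"],
        "b": {m: {k: float(v) for k, v in d.items()} for m, d in truth["b"].items()},
        "seed": config.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))

    files = sorted(
        [p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"]
    )
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "hashes": {str(p.relative_to(out)): _hash_file(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("simulate stage finished in %.1fs", time.time() - t0)
    data["manifest"] = manifest
    return data


def run_all(config: RunConfig, out_dir, skip_hotspots: bool = False) -> dict:
    """Execute every stage in order and write all reports.

    Returns the in-memory results dict (panel, metrics, hotspot tables,
    coefficient table, fits).
    """
    out = Path(out_dir)
    data = simulate_artifacts(config, out)
    stages: dict = dict(data)

    t0 = time.time()
    normalized = trajectories.normalize_to_baseline(
        data["daily_panel"], config.synthetic.baseline_date
    )
    monthly = trajectories.aggregate_monthly(normalized, *config.window)
    monthly.to_csv(out / "monthly_panel.csv", index=False)
    stages["monthly_panel"] = monthly
    turning = {
        mode: trajectories.find_turning_points(trajectories.mean_trajectory(monthly, mode))
        for mode in monthly["mode"].unique()
    }
    stages["turning_points"] = turning
    logger.info("trajectories stage finished in %.1fs", time.time() - t0)

    if not skip_hotspots:
        t0 = time.time()
        detail, summary = hotspot.hotspots_over_time(
            monthly, data["sites"], config.hotspot_scheme, config.hotspot_param
        )
        detail.to_csv(out / "hotspot_detail.csv", index=False)
        summary.to_csv(out / "hotspot_summary.csv", index=False)
        stages["hotspot_detail"], stages["hotspot_summary"] = detail, summary
        logger.info("hotspot stage finished in %.1fs", time.time() - t0)

    t0 = time.time()
    coef_table, fits = spatial_model.run_model_suite(
        monthly,
        data["metrics"],
        (data["static"], data["monthly_covariates"]),
        data["sites"],
        estimation=config.estimation,
    )
    coef_table.to_csv(out / "coefficients.csv", index=False)
    varcomp = {mid: fit.varcomp for mid, fit in fits.items()}
    (out / "varcomp.json").write_text(json.dumps(varcomp, indent=1))
    stages["coefficients"], stages["fits"] = coef_table, fits
    logger.info("model stage finished in %.1fs", time.time() - t0)

    (out / "summary.md").write_text(_summary_md(stages, skip_hotspots))
    return stages


def _summary_md(stages: dict, skip_hotspots: bool) -> str:
    lines = ["# Pipeline summary", ""]
    lines.append(f"Cities: {len(stages['sites'])}; monthly records: {len(stages['monthly_panel'])}")
    lines.append("")
    lines.append("## Turning points (month_index of strict local minima, mean trajectory)")
    for mode, pts in stages["turning_points"].items():
        months = stages["monthly_panel"]["month_index"].sort_values().unique()
        lines.append(f"- {mode}: {[int(months[i]) for i in pts]}")
    if not skip_hotspots:
        lines.append("")
        lines.append("## Hot/cold spot counts per mode x month")
        lines.append(stages["hotspot_summary"].to_string(index=False))
    lines.append("")
    lines.append("## Model suite coefficients")
    lines.append(stages["coefficients"].to_string(index=False))
    lines.append("")
    return "\n".join(lines)
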