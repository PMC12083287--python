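"""Generator contracts: determinism, degenerate inputs, generative moments."""

import numpy as np
import pandas as pd
import pytest

import greenmobility as gm
from greenmobility.distances import haversine_km
from greenmobility.synthetic import CITY_TYPES, apply_coefficients


class TestSites:
    def test_seeded_determinism(self):
        cfg = gm.SyntheticConfig(n_cities=5, seed=1)
        a = gm.generate_city_sites(cfg)
        b = gm.generate_city_sites(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_two_cities_rejected(self):
        with pytest.raises(ValueError, match="n_cities"):
            gm.SyntheticConfig(n_cities=2)

    def test_coordinates_in_range_and_distinct(self):
        sites = gm.generate_city_sites(gm.SyntheticConfig(n_cities=50, seed=7))
        assert sites["lon"].between(-180, 180).all()
        assert sites["lat"].between(-60, 75).all()
        assert sites["city_id"].is_unique
        d = haversine_km(sites["lon"], sites["lat"])
        assert (d[np.triu_indices(50, k=1)] > 0).all()

    def test_country_grouping(self):
        sites = gm.generate_city_sites(gm.SyntheticConfig(n_cities=50, seed=7))
        n_countries = sites["country_id"].nunique()
        assert 3 <= n_countries <= int(np.ceil(50 / 7))
        # singleton countries are merged away (they degenerate the design)
        assert sites["country_id"].value_counts().min() >= 2


class TestRasters:
    def test_seeded_determinism(self):
        cfg = gm.SyntheticConfig(grid_shape=(12, 12))
        a = gm.generate_city_raster(cfg, "c0", seed=9)
        b = gm.generate_city_raster(cfg, "c0", seed=9)
        np.testing.assert_array_equal(a.population, b.population)
        np.testing.assert_array_equal(a.green_fraction, b.green_fraction)

    def test_small_grid_rejected(self):
        cfg = gm.SyntheticConfig(grid_shape=(3, 8))
        with pytest.raises(ValueError, match="4x4"):
            gm.generate_city_raster(cfg, "c0", seed=0)

    def test_population_positive_and_clustered(self):
        cfg = gm.SyntheticConfig(grid_shape=(24, 24))
        r = gm.generate_city_raster(cfg, "c0", seed=3)
        assert (r.population > 0).all() and r.population.sum() > 0
        # Moran-style check: neighbouring cells more alike than the field sd
        lp = np.log(r.population)
        assert np.abs(np.diff(lp, axis=0)).mean() < lp.std()

    def test_saturated_quantiles_pin_exposure(self):
        all_green = gm.SyntheticConfig(
            grid_shape=(10, 10),
            green_field={"threshold_quantile": 0.0, "range_cells": 3.0, "quantile_jitter": 0.1},
        )
        r = gm.generate_city_raster(all_green, "c0", seed=1)
        assert gm.population_weighted_exposure(r, 500.0) == pytest.approx(1.0)
        no_green = gm.SyntheticConfig(
            grid_shape=(10, 10),
            green_field={"threshold_quantile": 1.0, "range_cells": 3.0, "quantile_jitter": 0.1},
        )
        r = gm.generate_city_raster(no_green, "c0", seed=1)
        assert gm.population_weighted_exposure(r, 500.0) == pytest.approx(0.0)


class TestCovariates:
    def test_shapes_and_ranges(self, small_config, small_dataset):
        static, monthly = small_dataset["static"], small_dataset["monthly_covariates"]
        assert len(static) == small_config.n_cities
        assert static["hdi"].between(0, 1).all()
        assert (static["density_k_km2"] > 0).all() and (static["pm25"] > 0).all()
        assert monthly["stringency"].between(0, 100).all()
        assert len(monthly) == small_config.n_cities * len(small_config.months)

    def test_infection_rate_cumulative(self, small_dataset):
        monthly = small_dataset["monthly_covariates"]
        for _, grp in monthly.sort_values("month").groupby("city_id"):
            assert (np.diff(grp["infection_rate"]) >= -1e-12).all()

    def test_city_type_levels(self, small_dataset):
        assert len(CITY_TYPES) == 8
        assert set(small_dataset["static"]["city_type"]) <= set(CITY_TYPES)

    def test_national_covariates_constant_within_country(self, small_dataset):
        static = small_dataset["static"]
        assert (static.groupby("country_id")[["gdp_kusd", "hdi"]].nunique() == 1).all().all()

    def test_empty_sites_rejected(self, small_config):
        with pytest.raises(ValueError, match="empty"):
            gm.generate_covariates(small_config, pd.DataFrame({"city_id": []}))


class TestPanel:
    def test_seeded_determinism(self, small_config, small_dataset):
        again = gm.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(small_dataset["daily_panel"], again["daily_panel"])

    def test_noiseless_limit_equals_linear_predictor(self):
        cfg = gm.SyntheticConfig(
            n_cities=5,
            grid_shape=(10, 10),
            var_components_true={"sigma_b_sq": 0.0, "rho_km": 800.0, "sigma_e_sq": 0.0},
            day_noise_sd=0.0,
            raw_scale_sd=0.0,
            seed=11,
        )
        data = gm.simulate_dataset(cfg)
        daily = data["daily_panel"]
        frame = gm.synthetic.covariate_frame(
            data["metrics"], data["static"], data["monthly_covariates"]
        )
        frame = frame[frame["month"].isin([str(m) for m in cfg.analysis_months])]
        frame = frame.sort_values(["city_id", "month"]).reset_index(drop=True)
        for mode in gm.MODES:
            expected = 100.0 + apply_coefficients(frame, cfg.coef_true[mode])
            sub = daily[daily["mode"] == mode].copy()
            sub["month"] = sub["date"].str.slice(0, 7)
            got = (
                sub[sub["month"] != "2020-01"]
                .groupby(["city_id", "month"])["index_value"]
                .mean()
                .sort_index()
            )
            np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-9)

    def test_unknown_predictor_rejected(self, small_config, small_dataset):
        cfg = gm.SyntheticConfig(
            n_cities=small_config.n_cities,
            grid_shape=small_config.grid_shape,
            coef_true={"walking": {"nonexistent": 1.0}},
            seed=1,
        )
        with pytest.raises(ValueError, match="unknown predictor"):
            gm.simulate_mobility_panel(
                small_dataset["sites"],
                small_dataset["metrics"],
                (small_dataset["static"], small_dataset["monthly_covariates"]),
                cfg,
            )

    def test_baseline_value_is_100_after_normalization(self, small_config, small_dataset):
        norm = gm.normalize_to_baseline(small_dataset["daily_panel"], small_config.baseline_date)
        at_base = norm[norm["date"] == small_config.baseline_date]
        assert len(at_base) == small_config.n_cities * 3
        np.testing.assert_allclose(at_base["index_value"], 100.0, atol=1e-9)


class TestGenerativeMoments:
    def test_spatial_effect_variance_matches_sigma_b_sq(self):
        rng = np.random.default_rng(12)
        sites = gm.generate_city_sites(gm.SyntheticConfig(n_cities=12, seed=3))
        sigma_b_sq, n_rep = 25.0, 500
        draws = np.array(
            [
                gm.draw_spatial_effects(
                    sites["lon"].to_numpy(), sites["lat"].to_numpy(), sigma_b_sq, 800.0, rng
                )
                for _ in range(n_rep)
            ]
        )
        per_city_var = draws.var(axis=0, ddof=1)
        # sampling sd of a sample variance of n_rep normals: sigma^2 sqrt(2/(n_rep-1))
        mc_se = sigma_b_sq * np.sqrt(2.0 / (n_rep - 1))
        assert abs(per_city_var.mean() - sigma_b_sq) < 3.0 * mc_se
        assert np.allclose(draws.mean(axis=0), 0.0, atol=3.0 * np.sqrt(sigma_b_sq / n_rep))

    def test_zero_variance_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        b = gm.draw_spatial_effects(np.array([0.0, 1.0, 2.0]), np.zeros(3), 0.0, 500.0, rng)
        np.testing.assert_array_equal(b, np.zeros(3))
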