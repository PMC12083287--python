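"""Design construction, VIF diagnostics and the spatial mixed-model fitter."""

import numpy as np
import pandas as pd
import pytest

import greenmobility as gm
from greenmobility.spatial_model import ModelSpec


@pytest.fixture(scope="module")
def design(small_monthly, small_dataset):
    spec = ModelSpec(response="walking")
    y, X, cids, dropped = gm.build_design(
        small_monthly,
        small_dataset["metrics"],
        (small_dataset["static"], small_dataset["monthly_covariates"]),
        spec,
    )
    return y, X, cids, dropped


class TestBuildDesign:
    def test_shape_contract(self, design, small_config):
        y, X, cids, dropped = design
        assert len(y) == 23 * small_config.n_cities
        assert dropped == 0
        assert "Intercept" in X.columns and (X["Intercept"] == 1).all()

    def test_interaction_column_is_centred_product(self, small_monthly, small_dataset):
        spec = ModelSpec(response="walking", interactions=[("exposure", "stringency")])
        _, X, _, _ = gm.build_design(
            small_monthly, small_dataset["metrics"],
            (small_dataset["static"], small_dataset["monthly_covariates"]), spec,
        )
        col = X["exposure:stringency"]
        manual = (X["exposure"] - X["exposure"].mean()) * (
            X["stringency"] - X["stringency"].mean()
        )
        np.testing.assert_allclose(col, manual, atol=1e-12)

    def test_listwise_deletion_drops_whole_city(self, small_monthly, small_dataset):
        static = small_dataset["static"].copy()
        static.loc[static.index[0], "hdi"] = np.nan
        spec = ModelSpec(response="walking")
        y, X, cids, dropped = gm.build_design(
            small_monthly, small_dataset["metrics"],
            (static, small_dataset["monthly_covariates"]), spec,
        )
        assert dropped == 23
        assert static.loc[static.index[0], "city_id"] not in set(cids)

    def test_unknown_term_rejected(self, small_monthly, small_dataset):
        spec = ModelSpec(response="walking", fixed_terms=["exposure", "wrong_name"])
        with pytest.raises(ValueError, match="wrong_name"):
            gm.build_design(
                small_monthly, small_dataset["metrics"],
                (small_dataset["static"], small_dataset["monthly_covariates"]), spec,
            )

    def test_interaction_member_must_be_fixed_term(self):
        with pytest.raises(ValueError, match="must appear in fixed_terms"):
            ModelSpec(response="walking", fixed_terms=["exposure"],
                      interactions=[("exposure", "gini")])


class TestVIF:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame(
            {
                "Intercept": np.ones(4),
                "a": [1.0, 1.0, -1.0, -1.0],
                "b": [1.0, -1.0, 1.0, -1.0],
                "c": [1.0, -1.0, -1.0, 1.0],
            }
        )
        s, mean = gm.vif(X)
        np.testing.assert_allclose(s.to_numpy(), 1.0, atol=1e-12)
        assert mean == pytest.approx(1.0)

    def test_duplicated_predictor_is_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = pd.DataFrame({"Intercept": np.ones(50), "x1": x, "x2": x,
                          "x3": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="collinearity"):
            s, _ = gm.vif(X)
        assert np.isinf(s["x1"]) and np.isinf(s["x2"])

    def test_matches_correlation_matrix_inverse(self):
        # identity: VIF_k = [inv(sample correlation of predictors)]_kk
        rng = np.random.default_rng(1)
        cov = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        Z = rng.multivariate_normal(np.zeros(3), cov, size=400)
        X = pd.DataFrame(Z, columns=["a", "b", "c"])
        X.insert(0, "Intercept", 1.0)
        s, _ = gm.vif(X)
        expected = np.diag(np.linalg.inv(np.corrcoef(Z, rowvar=False)))
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-8)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(2)
        Z = rng.normal(size=(120, 3))
        Z[:, 2] = 0.7 * Z[:, 0] + 0.3 * Z[:, 2]
        X = pd.DataFrame(Z, columns=["a", "b", "c"])
        X.insert(0, "Intercept", 1.0)
        s, _ = gm.vif(X)
        ref = [variance_inflation_factor(X.to_numpy(), j) for j in range(1, 4)]
        np.testing.assert_allclose(s.to_numpy(), ref, rtol=1e-8)

    def test_needs_two_predictors(self):
        X = pd.DataFrame({"Intercept": np.ones(5), "a": np.arange(5.0)})
        with pytest.raises(ValueError, match="at least 2"):
            gm.vif(X)


def _simulate_design(seed, n_cities=20, varcomp=None):
    cfg = gm.SyntheticConfig(
        n_cities=n_cities, grid_shape=(14, 14), seed=seed,
        var_components_true=varcomp or dict(gm.synthetic.DEFAULT_VARCOMP),
    )
    d = gm.simulate_dataset(cfg)
    monthly = gm.aggregate_monthly(gm.normalize_to_baseline(d["daily_panel"], cfg.baseline_date))
    y, X, cids, _ = gm.build_design(
        monthly, d["metrics"], (d["static"], d["monthly_covariates"]),
        ModelSpec(response="walking"),
    )
    return cfg, d, y, X, cids


class TestFit:
    def test_ols_limit_at_zero_spatial_variance(self):
        import statsmodels.api as sm

        _, d, y, X, cids = _simulate_design(
            seed=5, varcomp={"sigma_b_sq": 0.0, "rho_km": 800.0, "sigma_e_sq": 16.0}
        )
        fit = gm.fit_spatial_mixed(
            y, X, cids, d["sites"], fixed={"sigma_b_sq": 0.0, "rho_km": 800.0}
        )
        ols = sm.OLS(np.asarray(y, float), X.to_numpy()).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), ols.params, rtol=1e-5)
        np.testing.assert_allclose(fit.se.to_numpy(), ols.bse, rtol=1e-4)

    def test_planted_coefficients_recovered_within_wald_error(self):
        cfg, d, y, X, cids = _simulate_design(seed=6)
        fit = gm.fit_spatial_mixed(y, X, cids, d["sites"])
        truth = cfg.coef_true["walking"]
        for term in ("exposure", "gini", "stringency", "infection_rate"):
            assert abs(fit.beta[term] - truth[term]) < 4.0 * fit.se[term]
        assert fit.converged

    def test_row_permutation_invariance(self):
        _, d, y, X, cids = _simulate_design(seed=7)
        fit = gm.fit_spatial_mixed(y, X, cids, d["sites"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit_p = gm.fit_spatial_mixed(
            y.iloc[perm].reset_index(drop=True),
            X.iloc[perm].reset_index(drop=True),
            cids.iloc[perm].reset_index(drop=True),
            d["sites"],
        )
        # agreement up to optimizer stopping tolerance (row order only changes
        # floating-point summation order)
        np.testing.assert_allclose(fit_p.beta.to_numpy(), fit.beta.to_numpy(),
                                   rtol=1e-3, atol=1e-6)
        assert fit_p.loglik == pytest.approx(fit.loglik, rel=1e-9)

    def test_loglik_at_least_truth(self):
        cfg, d, y, X, cids = _simulate_design(seed=8)
        fit = gm.fit_spatial_mixed(y, X, cids, d["sites"])
        ll_truth = gm.profile_loglik(y, X, cids, d["sites"], cfg.var_components_true)
        assert fit.loglik >= ll_truth - 1e-6

    def test_duplicated_rows_keep_beta_and_structured_se(self):
        _, d, y, X, cids = _simulate_design(seed=9)
        fit = gm.fit_spatial_mixed(y, X, cids, d["sites"])
        dup = lambda s: pd.concat([s, s], ignore_index=True)
        fit2 = gm.fit_spatial_mixed(dup(y), dup(X), dup(cids), d["sites"])
        # beta essentially unchanged; city-level SEs must NOT shrink by
        # 1/sqrt(2) as they would under an independence (naive OLS) model,
        # because the fitted V keeps the city-level variance component
        assert (np.abs(fit2.beta - fit.beta) <= 0.35 * fit.se).all()
        assert fit2.se["exposure"] / fit.se["exposure"] > 0.85

    def test_rank_deficient_design_rejected(self, design, small_dataset):
        y, X, cids, _ = design
        X2 = X.copy()
        X2["dup"] = X2["exposure"]
        with pytest.raises(ValueError, match="rank deficient"):
            gm.fit_spatial_mixed(y, X2, cids, small_dataset["sites"])

    def test_unknown_fixed_component_rejected(self, design, small_dataset):
        y, X, cids, _ = design
        with pytest.raises(ValueError, match="unknown variance component"):
            gm.fit_spatial_mixed(y, X, cids, small_dataset["sites"], fixed={"nope": 1.0})


@pytest.fixture(scope="module")
def suite(small_monthly, small_dataset):
    return gm.run_model_suite(
        small_monthly,
        small_dataset["metrics"],
        (small_dataset["static"], small_dataset["monthly_covariates"]),
        small_dataset["sites"],
    )


class TestModelSuite:

    def test_suite_completeness(self, suite):
        table, fits = suite
        # 3 base models + (1 exposure x gini + 5 moderators) x 3 modes
        assert len(fits) == 21
        assert set(fits) == {"1", "2", "3"} | {
            f"{k}{s}" for k in range(4, 10) for s in "abc"
        }
        assert {"model_id", "response", "term", "estimate", "se", "z", "p", "stars"} <= set(
            table.columns
        )

    def test_moderation_models_contain_interactions(self, suite):
        table, _ = suite
        m9 = table[table["model_id"] == "9b"]
        assert "exposure:infection_rate" in set(m9["term"])
        assert "gini:infection_rate" in set(m9["term"])
        m4 = table[table["model_id"] == "4a"]
        assert "exposure:gini" in set(m4["term"])

    def test_stars_match_p_values(self, suite):
        table, _ = suite
        strong = table[table["p"] < 0.01]
        assert (strong["stars"] == "***").all()
        weak = table[table["p"] >= 0.10]
        assert (weak["stars"] == "").all()
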