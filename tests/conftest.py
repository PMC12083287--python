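import pytest

import greenmobility as gm


@pytest.fixture(scope="session")
def small_config() -> gm.SyntheticConfig:
    """Twenty-city study with the default 23-month window.

    The base model carries ~16 city-level columns (intercept, two green
    metrics, seven static covariates, up to seven urban-form dummies), so
    identifiability needs comfortably more cities than that — and at least
    three countries, else the two national-level covariates (GDP, HDI) span
    the same contrast.
    """
    return gm.SyntheticConfig(n_cities=20, grid_shape=(16, 16), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return gm.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_monthly(small_config, small_dataset):
    normalized = gm.normalize_to_baseline(
        small_dataset["daily_panel"], small_config.baseline_date
    )
    return gm.aggregate_monthly(normalized)
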