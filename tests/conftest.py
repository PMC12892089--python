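import dataclasses

import pytest

import heatmort as hm


@pytest.fixture(scope="session")
def small_config():
    """Two-region, seven-year Texas-like scenario used across tests."""
    return hm.ScenarioConfig(n_regions=2, years=(2012, 2018), seed=11)


@pytest.fixture(scope="session")
def small_temps(small_config):
    return hm.generate_temperature(small_config)


@pytest.fixture(scope="session")
def small_deaths(small_config, small_temps):
    return hm.generate_mortality(small_temps, small_config)


@pytest.fixture(scope="session")
def small_run_config(small_config):
    lo, hi = small_config.years
    return hm.RunConfig(
        climatology_window=(lo, hi), mmtd_fit_years=(lo + 1, hi - 1)
    )


@pytest.fixture(scope="session")
def small_model(small_temps, small_deaths, small_run_config):
    model = hm.HeatAttributionModel(config=small_run_config)
    return model.fit(small_temps, small_deaths)


@pytest.fixture(scope="session")
def reference_table():
    return hm.load_reference_table()
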