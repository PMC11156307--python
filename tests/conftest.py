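"""Shared fixtures: a small synthetic study system reused across modules."""

import pytest

from fishcast.config import ScenarioSpec, SyntheticConfig
from fishcast import synthetic


SMALL_SCENARIOS = (
    ScenarioSpec("SSP126", 1.0, 0.30, 0.05),
    ScenarioSpec("SSP245", 2.0, 0.50, 0.10),
    ScenarioSpec("SSP370", 3.0, 0.75, 0.15),
    ScenarioSpec("SSP585", 4.0, 0.90, 0.20),
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        lon_min=-180.0,
        lon_max=-170.0,
        lat_min=56.0,
        lat_max=64.0,
        fine_res=0.5,
        coarse_res=1.0,
        n_species=3,
        n_surveys_per_year=30,
        scenarios=SMALL_SCENARIOS,
        seed=11,
    )


@pytest.fixture(scope="session")
def climate(small_config):
    return synthetic.generate_environment(small_config)


@pytest.fixture(scope="session")
def niches(small_config):
    return synthetic.default_niches(small_config)


@pytest.fixture(scope="session")
def surveys(small_config, climate, niches):
    return synthetic.sample_surveys(climate.fine, niches, small_config)


@pytest.fixture(scope="session")
def ref_params(small_config):
    return synthetic.generate_reference_params(
        small_config.n_species, seed=small_config.seed
    )


@pytest.fixture(scope="session")
def geography(small_config, climate):
    return synthetic.generate_geography(small_config, climate.marine_mask)
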