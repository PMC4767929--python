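import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from altsem import (
    SimulationConfig, moments_from_raw, simulate_alt, table1_fixture,
)

settings.register_profile(
    "altsem", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("altsem")


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def small_config():
    """A small, fast ALT design used across modules: 5 days, one binary
    covariate, mild AR, moderate noise."""
    return SimulationConfig(
        T=5, n_per_cell=60, covariates=("stress",),
        intercept_mean=40.0, slope_mean=-2.0,
        gamma_icept={"stress": 2.0}, gamma_slope={"stress": 0.5},
        icept_sd=6.0, slope_sd=0.8, is_corr=0.1, rho=0.1,
        error_sd=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_alt(small_config)


@pytest.fixture(scope="session")
def small_moments(small_data):
    return moments_from_raw(small_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
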