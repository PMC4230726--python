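import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reactivepgg import GameParams, PopulationParams, run_sml

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# headline study conditions: Z=100, beta=1.0, F/N=0.85, w=0.96, eps=0.05
HEADLINE_KW = dict(f_over_n=0.85, w=0.96, eps=0.05)


@pytest.fixture(scope="session")
def headline_params() -> GameParams:
    return GameParams.from_f_over_n(5, **HEADLINE_KW)


@pytest.fixture(scope="session")
def pop100() -> PopulationParams:
    return PopulationParams(Z=100, beta=1.0)


@pytest.fixture(scope="session")
def headline_sml(headline_params, pop100):
    """Full 128-strategy small-mutation-limit run at the headline parameters."""
    return run_sml(headline_params, pop100, keep_pair_data=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
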