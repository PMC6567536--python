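import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mnarsim import (  # noqa: E402
    CompleteSample,
    MissingnessScenario,
    PopulationParams,
    generate_complete_sample,
)


@pytest.fixture(scope="session")
def default_params() -> PopulationParams:
    return PopulationParams()


@pytest.fixture(scope="session")
def big_sample(default_params) -> CompleteSample:
    """One large sample shared by the moment-convergence checks."""
    return generate_complete_sample(default_params, n=1_000_000, seed=20_240_101)


@pytest.fixture
def small_sample(default_params) -> CompleteSample:
    return generate_complete_sample(default_params, n=1000, seed=11)


@pytest.fixture
def mcar_scenario() -> MissingnessScenario:
    return MissingnessScenario(b_non1=0.0, b_non2=0.0, response_rate=0.70)
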