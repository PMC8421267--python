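import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from golgisort.simulate import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def proteome(default_config):
    from golgisort.simulate import simulate_proteome

    return simulate_proteome(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
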