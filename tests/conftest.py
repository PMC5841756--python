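import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hallerseg.io import PipelineConfig
from hallerseg.synth import PhantomSpec, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def phantom():
    """One deterministic mid-size phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noise_free_phantom():
    return generate_phantom(PhantomSpec(seed=7, noise_free=True))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
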