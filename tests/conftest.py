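import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mscds import GeneratorConfig, generate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """Two replicates per operator/density: fast but structurally complete."""
    return generate_experiment(GeneratorConfig(seed=11, replicates=2))


@pytest.fixture(scope="session")
def full_experiment():
    """The default study design (3 operators x 3 densities x 6 replicates)."""
    return generate_experiment(GeneratorConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
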