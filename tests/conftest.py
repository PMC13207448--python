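import pytest
from hypothesis import HealthCheck, settings

from sipref import (
    GradientConfig,
    build_profiles,
    random_community,
    simulate_experiment,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return GradientConfig(seed=42)


@pytest.fixture(scope="session")
def default_community():
    """50 soil-like taxa, 5 heavily labeled at >= 2% baseline abundance."""
    return random_community(seed=42)


@pytest.fixture(scope="session")
def default_experiment(default_community, default_config):
    return simulate_experiment(default_community, default_config)


@pytest.fixture(scope="session")
def default_profile(default_experiment):
    return build_profiles(
        default_experiment.fractions_12c, default_experiment.fractions_13c
    )
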