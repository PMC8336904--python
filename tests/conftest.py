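import pytest
from hypothesis import HealthCheck, settings

from depio import synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return sd.SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def economy(config):
    return sd.generate_economy(config)


@pytest.fixture(scope="session")
def profiles(config):
    return sd.generate_profiles(config)


@pytest.fixture(scope="session")
def specs(config):
    return sd.generate_benefit_specs(config)


@pytest.fixture(scope="session")
def bridge(config):
    return sd.generate_price_bridge(config)


@pytest.fixture(scope="session")
def fixture():
    return sd.published_tables()
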