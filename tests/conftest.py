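import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_config():
    from stentbim import default_imperial_config

    return default_imperial_config()


@pytest.fixture(scope="session")
def base_result(base_config):
    from stentbim import run_model

    return run_model(base_config)
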