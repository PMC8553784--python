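import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    from n15emerge import ParcelParams

    return ParcelParams()


@pytest.fixture(scope="session")
def default_trajectory(default_params):
    from n15emerge import run

    return run(default_params)


@pytest.fixture(scope="session")
def default_sweep(default_params):
    from n15emerge import upwelling_sweep

    return upwelling_sweep(default_params)
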