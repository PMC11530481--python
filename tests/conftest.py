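import pytest
from hypothesis import HealthCheck, settings

from pbpke.chem import Chemical, Environment

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def acetophenone() -> Chemical:
    return Chemical(
        name="Acetophenone", cas="98-86-2", mw=120.15, log_kow=0.20,
        vapour_pressure=52.90, density=1028.0,
    )


@pytest.fixture
def tolunitrile() -> Chemical:
    return Chemical(
        name="4-Tolunitrile", cas="104-85-8", mw=117.15, log_kow=1.58,
        vapour_pressure=41.72, density=978.0,
    )


@pytest.fixture
def water() -> Chemical:
    return Chemical(
        name="water", mw=18.015, log_kow=-1.38, vapour_pressure=4742.0,
        density=995.0, is_water=True,
    )


@pytest.fixture
def dry_env() -> Environment:
    return Environment(relative_humidity=0.0)
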