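import pytest
from hypothesis import HealthCheck, settings

from tuberflow import load_fixture
from tuberflow.weather import SeasonSpec, synthesize_season

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montcalm():
    return load_fixture("montcalm")


@pytest.fixture(scope="session")
def mecosta():
    return load_fixture("mecosta")


@pytest.fixture(scope="session")
def crop_params():
    return load_fixture("potato_2023")


@pytest.fixture(scope="session")
def calendar():
    return load_fixture("calendar_2023")


@pytest.fixture(scope="session")
def season_2023like():
    """Synthetic stand-in for the 2023 growing season (312.8 mm of rain)."""
    return synthesize_season(load_fixture("season_2023like"))


@pytest.fixture(scope="session")
def dry_season():
    return synthesize_season(SeasonSpec(target_rain_mm=220.0, seed=11))
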