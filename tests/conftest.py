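import numpy as np
import pytest

from mulchsim import scenario, weather


@pytest.fixture(scope="session")
def climate_spec():
    return weather.ClimateSpec()


@pytest.fixture(scope="session")
def weather_3y(climate_spec):
    """Three synthetic years of study-region weather (seeded)."""
    return weather.generate_weather(climate_spec, years=3, seed=0, start_year=2019)


@pytest.fixture(scope="session")
def climatology():
    """Study-era growing-season precipitation totals (2016-2023 record)."""
    from mulchsim import reference

    return sorted(reference.GROWING_SEASON_PRECIP_MM.values())


@pytest.fixture(scope="session")
def season_bm60(weather_3y):
    return scenario.run_season(scenario.ScenarioConfig(treatment="BM60"),
                               weather_3y, year=2019)


@pytest.fixture(scope="session")
def season_ck(weather_3y):
    return scenario.run_season(scenario.ScenarioConfig(treatment="CK"),
                               weather_3y, year=2019)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
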