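import numpy as np
import pandas as pd
import pytest

from riceclim.synthetic import WeatherGenParams, generate_daily_weather


@pytest.fixture(scope="session")
def default_params() -> WeatherGenParams:
    return WeatherGenParams(seed=7)


@pytest.fixture(scope="session")
def weather_10y(default_params) -> pd.DataFrame:
    """Ten years of daily weather under the default tropical conditions."""
    return generate_daily_weather(default_params, "2005-01-01", 3650)


@pytest.fixture(scope="session")
def weather_2y(default_params) -> pd.DataFrame:
    return generate_daily_weather(default_params, "2010-01-01", 760)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
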