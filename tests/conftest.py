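import numpy as np
import pytest

from eonrcast import (
    WeatherGenConfig,
    WeatherLibrary,
    WeatherSeries,
    generate_weather_library,
)
from eonrcast.weather import DAYS_PER_YEAR


def make_constant_series(
    year: int,
    tmean: float = 10.0,
    annual_precip: float = 900.0,
    radiation: float = 15.0,
    diurnal: float = 10.0,
    summer_tmean: float | None = None,
    summer_precip_total: float | None = None,
) -> WeatherSeries:
    """A hand-checkable series: constant days, optional distinct summer block."""
    t = np.full(DAYS_PER_YEAR, float(tmean))
    p = np.full(DAYS_PER_YEAR, annual_precip / DAYS_PER_YEAR)
    if summer_tmean is not None:
        t[151:243] = summer_tmean
    if summer_precip_total is not None:
        p[151:243] = summer_precip_total / 92.0
    return WeatherSeries(
        year_label=year,
        tmax=t + diurnal / 2,
        tmin=t - diurnal / 2,
        precip=p,
        radiation=np.full(DAYS_PER_YEAR, float(radiation)),
    )


@pytest.fixture(scope="session")
def small_lib() -> WeatherLibrary:
    """A 12-year synthetic library (fast fixture for forecast tests)."""
    return generate_weather_library(
        WeatherGenConfig(n_years=12, start_year=1995, seed=3)
    )


@pytest.fixture(scope="session")
def lib35() -> WeatherLibrary:
    """The full 35-year synthetic historical library."""
    return generate_weather_library(WeatherGenConfig(seed=11))


@pytest.fixture()
def quadrant_lib() -> WeatherLibrary:
    """Hand-built library with known anomaly quadrants.

    Long-term means: temp (10+10.2+10.4+8+8.2+10.5)/6 = 9.55 degC,
    precip (1000+1020+990+800+820+1050)/6 = 946.67 mm. Hence 2001-2003 and
    2006 are warm/wet; 2004-2005 are cold/dry.
    """
    lib = WeatherLibrary()
    spec = {
        2001: (10.0, 1000.0),
        2002: (10.2, 1020.0),
        2003: (10.4, 990.0),
        2004: (8.0, 800.0),
        2005: (8.2, 820.0),
        2006: (10.5, 1050.0),
    }
    for year, (t, p) in spec.items():
        lib.add(make_constant_series(year, tmean=t, annual_precip=p))
    return lib
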