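import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import poa_emergence as pe

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_weather(
    temps, start="2019-06-21", site_id="siteA", rainfall=None, soil=None
) -> pe.WeatherSeries:
    """Daily weather series from a plain list of mean air temperatures."""
    temps = list(temps)
    dates = pd.date_range(start, periods=len(temps), freq="D")
    data = {"date": dates, "t_air_mean": temps}
    if rainfall is not None:
        data["rainfall"] = list(rainfall)
    if soil is not None:
        data["t_soil_5cm"] = list(soil)
    return pe.WeatherSeries(site_id, pd.DataFrame(data))


def make_curve(dates, counts, cdd=None, site_id="siteA", year=2019) -> pe.EmergenceCurve:
    """Emergence curve built directly from observation dates and counts."""
    dates = pd.to_datetime(list(dates))
    counts = np.asarray(counts, dtype=int)
    cum = np.cumsum(counts)
    total = int(cum[-1])
    if cdd is None:
        cdd = np.arange(len(counts), dtype=float) * 10.0
    data = pd.DataFrame(
        {
            "date": dates,
            "cdd": np.asarray(cdd, dtype=float),
            "cum_count": cum,
            "cum_fraction": cum / total,
        }
    )
    return pe.EmergenceCurve(
        site_id=site_id, season_year=year, yearly_total=total, data=data
    )


@pytest.fixture(scope="session")
def sim_config() -> pe.SimulationConfig:
    return pe.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def sim_weather(sim_config):
    return pe.simulate_weather(sim_config)["site01"]


@pytest.fixture(scope="session")
def sim_records(sim_config, sim_weather):
    return pe.simulate_emergence(sim_weather, sim_config)


@pytest.fixture(scope="session")
def sim_tts(sim_config, sim_weather):
    return pe.accumulate(sim_weather, anchor_date=sim_config.anchor_date)


@pytest.fixture(scope="session")
def sim_curve(sim_records, sim_tts, sim_config):
    return pe.build_curve(sim_records, sim_tts, sim_config.season_year)
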