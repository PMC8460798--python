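"""Synthetic weather, emergence observations, and predictor matrices.

Every pipeline stage in this package is testable without field data: the
generator emits daily weather for a temperate mid-South annual cycle,
seedling-count observations whose cumulative fraction follows a known
thermal-time emergence model (the ground truth), and predictor matrices
with one series built to a target Pearson correlation.

The observation model mirrors the destructive-count protocol: the site
seedbank holds N seeds; over each observation interval the count of new
seedlings is Binomial(N_plot, ΔF), where ΔF is the increment of the true
cumulative emergence fraction over the interval (equivalently multinomial
over the season). Counts are exhaustive — every emerged seedling is seen
once. The sampling cadence defaults to the monitored-study schedule:
weekly January–May, biweekly June–August, weekly September–December.

Rainfall is generated but does not feed the emergence model (the
emergence truth is thermal-time-only); a moisture-modulation hook exists
for extensions but defaults off.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field as _field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .thermal_time import (
    DEFAULT_BASE_TEMP,
    ThermalTimeSeries,
    WeatherSeries,
    accumulate,
    summer_solstice,
)

__all__ = [
    "TempModel",
    "RainModel",
    "TrueModel",
    "CadenceBlock",
    "SimulationConfig",
    "STUDY_CADENCE",
    "observation_dates",
    "simulate_weather",
    "simulate_emergence",
    "simulate_predictors",
]


@dataclass(frozen=True)
class TempModel:
    """Annual air-temperature cycle parameters (°C, day-of-year)."""

    annual_mean: float = 15.0
    annual_amplitude: float = 11.0
    phase_doy: int = 201  # warmest day of year (late July)
    noise_sd: float = 2.0
    soil_lag_days: int = 2  # soil follows a lagged smoothed air series
    diurnal_half_range: float = 5.0  # air min/max offset about the mean


@dataclass(frozen=True)
class RainModel:
    """Episodic rainfall: Bernoulli wet days with exponential depths."""

    wet_prob: float = 0.30
    wet_mean_mm: float = 9.0


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth emergence curve on the fraction-of-seedbank scale."""

    kind: _models.ModelKind = "gompertz"
    a: float = 0.485
    b: float = 12.141
    c: float = 0.081

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def fraction(self, cdd) -> np.ndarray:
        """Cumulative fraction of the seedbank, clipped to [0, 1]."""
        return np.clip(
            _models.evaluate(self.kind, cdd, self.a, self.b, self.c), 0.0, 1.0
        )


@dataclass(frozen=True)
class CadenceBlock:
    """One block of the observation schedule: (month, day) bounds and
    visit interval in days."""

    start: tuple[int, int]
    end: tuple[int, int]
    interval_days: int


#: Weekly Jan 1–May 31, biweekly Jun 1–Aug 31, weekly Sep 1–Dec 31.
STUDY_CADENCE: tuple[CadenceBlock, ...] = (
    CadenceBlock((1, 1), (5, 31), 7),
    CadenceBlock((6, 1), (8, 31), 14),
    CadenceBlock((9, 1), (12, 31), 7),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, reproducible from ``seed``."""

    seed: int = 0
    n_sites: int = 1
    season_year: int = 2019
    temp: TempModel = _field(default_factory=TempModel)
    rain: RainModel = _field(default_factory=RainModel)
    true_model: TrueModel = _field(default_factory=TrueModel)
    seedbank_n: int = 10_000
    n_plots: int = 4
    cadence: tuple[CadenceBlock, ...] = STUDY_CADENCE
    base_temp: float = DEFAULT_BASE_TEMP
    anchor_month_day: tuple[int, int] = (6, 21)
    moisture_modulation: Callable[[pd.Series], pd.Series] | None = None

    def __post_init__(self) -> None:
        if self.seedbank_n <= 0:
            raise ValueError("seedbank_n must be positive")
        if not (0 <= self.rain.wet_prob <= 1):
            raise ValueError("wet_prob must lie in [0, 1]")
        if self.temp.annual_amplitude < 0:
            raise ValueError("annual_amplitude must be non-negative")
        if self.n_plots <= 0:
            raise ValueError("n_plots must be positive")

    @property
    def anchor_date(self) -> _dt.date:
        return _dt.date(self.season_year, *self.anchor_month_day)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _site_rngs(config: SimulationConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(config.n_sites)
    return [np.random.default_rng(s) for s in children]


def observation_dates(
    year: int, cadence: Sequence[CadenceBlock] = STUDY_CADENCE
) -> list[_dt.date]:
    """Visit dates implied by a cadence schedule for one calendar year."""
    dates: list[_dt.date] = []
    for block in cadence:
        start = _dt.date(year, *block.start)
        end = _dt.date(year, *block.end)
        d = start
        while d <= end:
            dates.append(d)
            d += _dt.timedelta(days=block.interval_days)
    return sorted(set(dates))


def simulate_weather(config: SimulationConfig) -> dict[str, WeatherSeries]:
    """Daily weather for each site over the full calendar season year.

    Air temperature is a cosine annual cycle plus Gaussian day noise; soil
    temperature at 5 cm is a lagged 3-day moving average of air (a
    parameterized placeholder for thermal inertia); rainfall is a
    Bernoulli wet-day indicator times an exponential depth with the
    configured wet-day mean. Fully reproducible from the seed.
    """
    out: dict[str, WeatherSeries] = {}
    year = config.season_year
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    tm = config.temp
    for i, rng in enumerate(_site_rngs(config)):
        site = f"site{i + 1:02d}"
        seasonal = tm.annual_mean + tm.annual_amplitude * np.cos(
            2 * np.pi * (doy - tm.phase_doy) / 365.0
        )
        noise = rng.normal(0.0, tm.noise_sd, size=len(dates)) if tm.noise_sd > 0 else 0.0
        t_air = seasonal + noise
        half = tm.diurnal_half_range
        t_min = t_air - half - np.abs(rng.normal(0.0, 0.5, size=len(dates)))
        t_max = t_air + half + np.abs(rng.normal(0.0, 0.5, size=len(dates)))
        air = pd.Series(t_air, index=dates)
        soil = (
            air.rolling(3, min_periods=1).mean().shift(tm.soil_lag_days).bfill()
        )
        wet = rng.random(len(dates)) < config.rain.wet_prob
        depth = rng.exponential(config.rain.wet_mean_mm, size=len(dates))
        rain = np.where(wet, depth, 0.0)
        rain_series = pd.Series(rain, index=dates)
        # simple bounded moisture response to the last week's rain
        moisture = np.clip(
            0.12 + 0.015 * rain_series.rolling(7, min_periods=1).mean(), 0.0, 1.0
        )
        dli = np.clip(
            22.0
            + 14.0 * np.cos(2 * np.pi * (doy - 172) / 365.0)
            + rng.normal(0.0, 2.0, size=len(dates)),
            0.0,
            None,
        ) / 2.0
        out[site] = WeatherSeries(
            site,
            pd.DataFrame(
                {
                    "date": dates,
                    "t_air_mean": t_air,
                    "t_air_min": t_min,
                    "t_air_max": t_max,
                    "t_soil_5cm": soil.to_numpy(),
                    "rainfall": rain,
                    "soil_moisture": moisture.to_numpy(),
                    "dli": dli,
                }
            ),
        )
    return out


def simulate_emergence(
    weather: dict[str, WeatherSeries] | WeatherSeries,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Dated new-seedling counts under the configured true model.

    For each site, cooling degree days accumulate from the anchor; the
    true cumulative fraction F is evaluated at each visit's thermal time
    (0 before the anchor); each plot's interval count is
    Binomial(seedbank_n // n_plots, F(t_i) − F(t_{i−1})). Returns records
    with columns site_id, plot_id, date, new_seedlings.
    """
    if isinstance(weather, WeatherSeries):
        weather = {weather.site_id: weather}
    rngs = _site_rngs(config)
    obs = observation_dates(config.season_year, config.cadence)
    rows = []
    plot_n = config.seedbank_n // config.n_plots
    for i, (site, ws) in enumerate(sorted(weather.items())):
        rng = rngs[i % len(rngs)]
        # independent stream for counts so weather and counts can be
        # redrawn separately without coupling
        count_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        if obs[0] < ws.start or obs[-1] > ws.end:
            raise ValueError(
                f"observation schedule {obs[0]}..{obs[-1]} outside weather span "
                f"[{ws.start}, {ws.end}] for site {site!r}"
            )
        tts = accumulate(
            ws,
            base_temp=config.base_temp,
            anchor_date=config.anchor_date,
            direction="below_base",
        )
        fracs = _visit_fractions(obs, tts, config.true_model)
        dF = np.diff(fracs, prepend=0.0)
        if config.moisture_modulation is not None:  # extension hook, off by default
            mod = config.moisture_modulation(ws.column("soil_moisture"))
            factors = np.array(
                [float(mod.asof(pd.Timestamp(d))) for d in obs], dtype=float
            )
            dF = np.clip(dF * factors, 0.0, None)
        for p in range(config.n_plots):
            counts = count_rng.binomial(plot_n, np.clip(dF, 0.0, 1.0))
            for d, k in zip(obs, counts):
                rows.append(
                    {
                        "site_id": site,
                        "plot_id": f"plot{p + 1}",
                        "date": pd.Timestamp(d),
                        "new_seedlings": int(k),
                    }
                )
    return pd.DataFrame(rows, columns=["site_id", "plot_id", "date", "new_seedlings"])


def _visit_fractions(
    obs: Sequence[_dt.date], tts: ThermalTimeSeries, true_model: TrueModel
) -> np.ndarray:
    anchor = tts.anchor_date
    cdd = np.array(
        [tts.thermal_time_at(d) if d >= anchor else np.nan for d in obs], dtype=float
    )
    fracs = np.where(np.isnan(cdd), 0.0, true_model.fraction(np.nan_to_num(cdd)))
    return fracs


def simulate_predictors(
    seed: int,
    n: int,
    k: int = 25,
    target_r: float = 0.90,
    designated: str = "cdd_accumulation_change",
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor matrix with one series at a target correlation.

    ``k`` candidate predictors (stand-ins for screened environmental
    parameters) of length ``n``: the designated one has population Pearson
    correlation ``target_r`` with the response; the rest are independent
    standard-normal noise. Screening should rank the designated predictor
    first with high probability.
    """
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("target_r must lie in [−1, 1]")
    if k < 1 or n < 3:
        raise ValueError("need k ≥ 1 predictors and n ≥ 3 samples")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    response = pd.Series(z, name="emergence_change")
    cols = {}
    eps = rng.standard_normal(n)
    cols[designated] = target_r * z + np.sqrt(max(0.0, 1 - target_r**2)) * eps
    for j in range(k - 1):
        cols[f"env_param_{j + 1:02d}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), response
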