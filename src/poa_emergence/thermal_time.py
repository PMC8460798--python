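"""Degree-day accumulation from daily weather records.

Annual bluegrass (*Poa annua*) emerges in autumn as temperatures fall, so
its thermal clock runs on *cooling* degree days: each day contributes the
number of degrees the daily mean temperature sits *below* a base (21 °C in
this package's defaults), summed from an anchor date (the summer solstice).
The conventional growing-degree-day direction (degrees above base) is
available through the ``direction`` argument so the same machinery covers
heat-driven phenology.

The central objects are :class:`WeatherSeries` (validated per-site daily
weather) and :class:`ThermalTimeSeries` (per-day increments plus the
running accumulation). :func:`accumulate` maps one onto the other;
:func:`date_at_thermal_time` and :func:`thermal_time_at_date` translate
between calendar dates and degree-day totals.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "ThermalTimeSeries",
    "daily_mean_temperature",
    "accumulate",
    "date_at_thermal_time",
    "thermal_time_at_date",
    "read_weather_csv",
    "write_weather_csv",
    "read_thermal_csv",
    "write_thermal_csv",
    "DEFAULT_BASE_TEMP",
    "summer_solstice",
]

logger = logging.getLogger(__name__)

#: Base temperature (°C) of the cooling-degree-day scale used throughout.
DEFAULT_BASE_TEMP = 21.0

Direction = Literal["below_base", "above_base"]

WEATHER_COLUMNS = [
    "site_id",
    "date",
    "t_air_mean",
    "t_air_min",
    "t_air_max",
    "t_soil_5cm",
    "rainfall",
    "soil_moisture",
    "dli",
]

_OPTIONAL_FIELDS = ["t_air_min", "t_air_max", "t_soil_5cm", "rainfall", "soil_moisture", "dli"]


def summer_solstice(year: int) -> _dt.date:
    """Default accumulation anchor: June 21 (northern hemisphere).

    The astronomical solstice falls on June 20 in some years; the fixed
    calendar date is used for reproducibility and can be overridden
    wherever an anchor is accepted.
    """
    return _dt.date(year, 6, 21)


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


@dataclass
class WeatherSeries:
    """One reconciled daily environmental record for a single site.

    ``data`` holds one row per calendar day with a ``date`` column
    (datetime64, midnight-normalized) plus any of: ``t_air_mean``,
    ``t_air_min``, ``t_air_max`` (°C), ``t_soil_5cm`` (°C at 5 cm depth),
    ``rainfall`` (mm/day), ``soil_moisture`` (volumetric fraction),
    ``dli`` (mol m⁻² d⁻¹). Validation enforces strictly increasing,
    duplicate-free dates, non-negative rainfall, soil moisture in [0, 1],
    and t_air_min ≤ t_air_mean ≤ t_air_max wherever all three are present.
    """

    site_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "date" not in df.columns:
            raise ValueError("weather data requires a 'date' column")
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df = df.sort_values("date").reset_index(drop=True)
        if df["date"].duplicated().any():
            dupes = df.loc[df["date"].duplicated(), "date"].dt.date.unique()
            raise ValueError(f"duplicate dates for site {self.site_id!r}: {list(dupes)}")
        if "rainfall" in df.columns:
            rain = df["rainfall"].dropna()
            if (rain < 0).any():
                raise ValueError("rainfall must be non-negative")
        if "soil_moisture" in df.columns:
            sm = df["soil_moisture"].dropna()
            if ((sm < 0) | (sm > 1)).any():
                raise ValueError("soil_moisture must lie in [0, 1]")
        if {"t_air_min", "t_air_mean", "t_air_max"}.issubset(df.columns):
            trio = df[["t_air_min", "t_air_mean", "t_air_max"]].dropna()
            bad = (trio["t_air_min"] > trio["t_air_mean"]) | (trio["t_air_mean"] > trio["t_air_max"])
            if bad.any():
                raise ValueError("t_air_min ≤ t_air_mean ≤ t_air_max violated")
        self.data = df

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    @property
    def start(self) -> _dt.date:
        return self.data["date"].iloc[0].date()

    @property
    def end(self) -> _dt.date:
        return self.data["date"].iloc[-1].date()

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"weather for site {self.site_id!r} has no field {name!r}")
        return self.data.set_index("date")[name]


@dataclass
class ThermalTimeSeries:
    """Per-day degree-day increments and running accumulation for one site.

    ``data`` has columns ``date``, ``increment`` (degree-days, ≥ 0) and
    ``cumulative`` (running sum from ``anchor_date``, the anchor day
    included).
    """

    site_id: str
    anchor_date: _dt.date
    base_temp: float
    direction: Direction
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        if (df["increment"] < 0).any():
            raise ValueError("degree-day increments must be non-negative")
        if (df["cumulative"].diff().dropna() < -1e-9).any():
            raise ValueError("cumulative degree-days must be non-decreasing")
        self.data = df.reset_index(drop=True)

    @property
    def final_cumulative(self) -> float:
        return float(self.data["cumulative"].iloc[-1])

    def thermal_time_at(self, date) -> float:
        return thermal_time_at_date(self, date)

    def date_at(self, target: float) -> _dt.date:
        return date_at_thermal_time(self, target)


def daily_mean_temperature(
    readings: Iterable[Tuple[object, float]] | pd.DataFrame,
    convention: Literal["mean_of_readings", "minmax_midpoint"] = "mean_of_readings",
) -> pd.Series:
    """Reduce sub-daily temperature readings to one daily value.

    ``mean_of_readings`` is the arithmetic mean of every reading that day;
    ``minmax_midpoint`` is (daily min + daily max)/2, the classical
    degree-day convention for stations that log only extremes. Returns a
    Series indexed by normalized date. Non-finite readings are rejected.
    """
    if isinstance(readings, pd.DataFrame):
        frame = readings.iloc[:, :2].copy()
        frame.columns = ["timestamp", "value"]
    else:
        frame = pd.DataFrame(list(readings), columns=["timestamp", "value"])
    if frame.empty:
        return pd.Series(dtype=float, name="t_mean")
    values = pd.to_numeric(frame["value"], errors="coerce")
    if not np.isfinite(values).all():
        raise ValueError("non-finite temperature reading in input")
    frame["value"] = values
    frame["day"] = pd.to_datetime(frame["timestamp"]).dt.normalize()
    grouped = frame.groupby("day")["value"]
    if convention == "mean_of_readings":
        out = grouped.mean()
    elif convention == "minmax_midpoint":
        out = (grouped.min() + grouped.max()) / 2.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    out.name = "t_mean"
    out.index.name = "date"
    return out


def accumulate(
    weather: WeatherSeries,
    base_temp: float = DEFAULT_BASE_TEMP,
    anchor_date=None,
    direction: Direction = "below_base",
    temp_field: str = "t_air_mean",
) -> ThermalTimeSeries:
    """Accumulate degree days from ``anchor_date`` onward.

    The daily increment is ``max(0, base − T)`` for ``below_base``
    (cooling degree days) or ``max(0, T − base)`` for ``above_base``
    (growing degree days), using the daily value in ``temp_field``. The
    anchor day itself is the first accumulation day. Days before the
    anchor are excluded. A missing calendar day or missing temperature
    inside the range is a hard error — silent gaps would drift the totals.
    """
    if not np.isfinite(base_temp):
        raise ValueError("base_temp must be finite")
    if direction not in ("below_base", "above_base"):
        raise ValueError(f"unknown direction {direction!r}")
    if anchor_date is None:
        anchor_date = summer_solstice(weather.start.year)
    anchor = _as_date(anchor_date)
    if anchor < weather.start or anchor > weather.end:
        raise ValueError(
            f"anchor_date {anchor} outside weather range "
            f"[{weather.start}, {weather.end}] for site {weather.site_id!r}"
        )
    temps = weather.column(temp_field)
    sub = temps[temps.index >= pd.Timestamp(anchor)]
    expected = pd.date_range(pd.Timestamp(anchor), sub.index[-1], freq="D")
    missing = expected.difference(sub.index)
    if len(missing):
        gaps = ", ".join(str(d.date()) for d in missing[:5])
        raise ValueError(
            f"weather for site {weather.site_id!r} is missing day(s) {gaps}"
            + ("…" if len(missing) > 5 else "")
            + " inside the accumulation range"
        )
    if sub.isna().any():
        bad = sub.index[sub.isna()][0].date()
        raise ValueError(
            f"missing {temp_field!r} value on {bad} for site {weather.site_id!r}"
        )
    t = sub.to_numpy(dtype=float)
    if direction == "below_base":
        inc = np.maximum(0.0, base_temp - t)
    else:
        inc = np.maximum(0.0, t - base_temp)
    data = pd.DataFrame(
        {"date": sub.index, "increment": inc, "cumulative": np.cumsum(inc)}
    )
    return ThermalTimeSeries(
        site_id=weather.site_id,
        anchor_date=anchor,
        base_temp=float(base_temp),
        direction=direction,
        data=data,
    )


def thermal_time_at_date(tts: ThermalTimeSeries, date) -> float:
    """Cumulative degree days on an exact calendar day in the series."""
    day = pd.Timestamp(_as_date(date))
    match = tts.data.loc[tts.data["date"] == day, "cumulative"]
    if match.empty:
        raise KeyError(
            f"{day.date()} not in thermal-time series for site {tts.site_id!r} "
            f"(covers {tts.data['date'].iloc[0].date()}..{tts.data['date'].iloc[-1].date()})"
        )
    return float(match.iloc[0])


def date_at_thermal_time(tts: ThermalTimeSeries, target: float) -> _dt.date:
    """First calendar day whose cumulative degree days reach ``target``."""
    if target < 0:
        raise ValueError("target degree days must be non-negative")
    cum = tts.data["cumulative"].to_numpy()
    idx = np.searchsorted(cum, target, side="left")
    if idx >= len(cum):
        raise ValueError(
            f"{target} degree days not reached in series "
            f"(final cumulative = {cum[-1]:.3f})"
        )
    return tts.data["date"].iloc[int(idx)].date()


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_weather_csv(path) -> dict[str, WeatherSeries]:
    """Read the one-row-per-site-day weather CSV into per-site series.

    Expected header: site_id,date,t_air_mean,t_air_min,t_air_max,
    t_soil_5cm,rainfall,soil_moisture,dli (ISO dates, empty cell =
    missing optional field). Columns absent from the file are tolerated.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    if "site_id" not in df.columns:
        raise ValueError("weather CSV requires a 'site_id' column")
    out: dict[str, WeatherSeries] = {}
    for site_id, grp in df.groupby("site_id", sort=True):
        out[str(site_id)] = WeatherSeries(str(site_id), grp.drop(columns="site_id"))
    return out


def write_weather_csv(series: Mapping[str, WeatherSeries] | Sequence[WeatherSeries], path) -> None:
    if isinstance(series, Mapping):
        series = list(series.values())
    frames = []
    for ws in series:
        df = ws.data.copy()
        df.insert(0, "site_id", ws.site_id)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    for col in WEATHER_COLUMNS:
        if col not in combined.columns:
            combined[col] = np.nan
    combined = combined[WEATHER_COLUMNS]
    combined["date"] = combined["date"].dt.strftime("%Y-%m-%d")
    combined.to_csv(path, index=False, float_format="%.6g")


def write_thermal_csv(tts: ThermalTimeSeries, path) -> None:
    df = tts.data.copy()
    df.insert(0, "site_id", tts.site_id)
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    header = (
        f"# anchor_date={tts.anchor_date.isoformat()} base_temp={tts.base_temp} "
        f"direction={tts.direction}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")


def read_thermal_csv(path) -> ThermalTimeSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("thermal-time CSV missing metadata header line")
        meta = dict(tok.split("=", 1) for tok in first.lstrip("#").split())
        df = pd.read_csv(fh, parse_dates=["date"])
    site = str(df["site_id"].iloc[0])
    return ThermalTimeSeries(
        site_id=site,
        anchor_date=_dt.date.fromisoformat(meta["anchor_date"]),
        base_temp=float(meta["base_temp"]),
        direction=meta["direction"],  # type: ignore[arg-type]
        data=df.drop(columns="site_id"),
    )
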