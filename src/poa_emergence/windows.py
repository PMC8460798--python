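"""Peak-emergence windows, rapid-change weeks, and edaphic summaries.

Management interventions against autumn-emerging *Poa annua* are timed to
the short period when emergence changes fastest. This module finds:

* the contiguous multi-week window (default 4 weeks) capturing the
  largest share of a season's total emergence, with the weather observed
  inside it;
* the week-of-year span where emergence changes most rapidly across
  several site-years, with per-week percentile summaries of the weekly
  shares (the box-plot style view);
* trailing rolling means of soil temperature and rainfall (default 7-day)
  and their across-site-year summaries over a date range.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .emergence import EmergenceCurve
from .thermal_time import WeatherSeries

__all__ = [
    "PeakWindow",
    "EdaphicSummary",
    "peak_window",
    "rapid_change_weeks",
    "RapidChangeResult",
    "rolling_edaphic",
    "summarize_edaphic",
    "day_night_means",
]


@dataclass
class PeakWindow:
    """A contiguous high-emergence period within one site-year.

    ``share`` is the fraction of the yearly total emerging inside
    [start_date, end_date]; ``cdd_span`` brackets the thermal time of the
    observations inside the window. Day/night air means are None unless
    sub-daily readings were supplied.
    """

    site_id: str
    season_year: int
    start_date: _dt.date
    end_date: _dt.date
    length_weeks: int
    share: float
    cdd_span: tuple[float, float]
    mean_air_temp: float | None = None
    mean_soil_temp: float | None = None
    total_rainfall: float | None = None
    day_air_temp: float | None = None
    night_air_temp: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.share <= 1.0 + 1e-12):
            raise ValueError("window share must lie in [0, 1]")
        if self.start_date > self.end_date:
            raise ValueError("window start must not follow its end")

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "season_year": self.season_year,
            "start_date": self.start_date.isoformat(),
            "end_date": self.end_date.isoformat(),
            "length_weeks": self.length_weeks,
            "share": self.share,
            "cdd_span": list(self.cdd_span),
            "mean_air_temp": self.mean_air_temp,
            "mean_soil_temp": self.mean_soil_temp,
            "total_rainfall": self.total_rainfall,
            "day_air_temp": self.day_air_temp,
            "night_air_temp": self.night_air_temp,
        }


@dataclass
class EdaphicSummary:
    """Rolling soil-temperature / rainfall means over a window, with the
    across-site-year spread (population sd; 0 for a single series)."""

    start: _dt.date
    end: _dt.date
    soil_temp_7d_mean: float
    soil_temp_spread: float
    rainfall_7d_mean: float
    rainfall_spread: float

    def __post_init__(self) -> None:
        if self.soil_temp_spread < 0 or self.rainfall_spread < 0:
            raise ValueError("spread must be non-negative")

    def to_dict(self) -> dict:
        return {
            "start": self.start.isoformat(),
            "end": self.end.isoformat(),
            "soil_temp_7d_mean": self.soil_temp_7d_mean,
            "soil_temp_spread": self.soil_temp_spread,
            "rainfall_7d_mean": self.rainfall_7d_mean,
            "rainfall_spread": self.rainfall_spread,
        }


def peak_window(
    curve: EmergenceCurve,
    weather: WeatherSeries | None = None,
    weeks: int = 4,
    subdaily_air: pd.DataFrame | None = None,
) -> PeakWindow:
    """Window of ``weeks`` weeks capturing the largest emerged share.

    Candidate windows start at each observation date and extend
    ``weeks × 7`` days (sliding over observation dates, matching the
    weekly sampling design). Ties break to the earliest start. Weather
    summaries (mean air temp, mean soil temp, total rainfall) are computed
    over the window's calendar days when ``weather`` is given; day/night
    air means additionally require ``subdaily_air`` (timestamp, °C).
    """
    if weeks < 1:
        raise ValueError("weeks must be ≥ 1")
    dates = curve.data["date"]
    span_days = (dates.iloc[-1] - dates.iloc[0]).days
    if span_days < weeks * 7:
        raise ValueError(
            f"curve spans {span_days} days, shorter than the {weeks}-week window"
        )
    counts = curve.counts.to_numpy(dtype=float)
    length = pd.Timedelta(days=weeks * 7)
    best_share, best_start = -1.0, None
    for start in dates:
        inside = (dates >= start) & (dates < start + length)
        share = counts[inside.to_numpy()].sum() / curve.yearly_total
        if share > best_share + 1e-15:
            best_share, best_start = share, start
    assert best_start is not None
    end = best_start + length - pd.Timedelta(days=1)
    inside = (dates >= best_start) & (dates <= end)
    cdd_inside = curve.data.loc[inside, "cdd"]
    cdd_span = (float(cdd_inside.iloc[0]), float(cdd_inside.iloc[-1]))

    mean_air = mean_soil = rain_total = day_t = night_t = None
    if weather is not None:
        wdf = weather.data
        in_win = (wdf["date"] >= best_start) & (wdf["date"] <= end)
        sub = wdf.loc[in_win]
        if "t_air_mean" in sub.columns and sub["t_air_mean"].notna().any():
            mean_air = float(sub["t_air_mean"].mean())
        if "t_soil_5cm" in sub.columns and sub["t_soil_5cm"].notna().any():
            mean_soil = float(sub["t_soil_5cm"].mean())
        if "rainfall" in sub.columns and sub["rainfall"].notna().any():
            rain_total = float(sub["rainfall"].sum())
    if subdaily_air is not None:
        day_t, night_t = day_night_means(
            subdaily_air, window=(best_start.date(), end.date())
        )

    return PeakWindow(
        site_id=curve.site_id,
        season_year=curve.season_year,
        start_date=best_start.date(),
        end_date=end.date(),
        length_weeks=weeks,
        share=float(best_share),
        cdd_span=cdd_span,
        mean_air_temp=mean_air,
        mean_soil_temp=mean_soil,
        total_rainfall=rain_total,
        day_air_temp=day_t,
        night_air_temp=night_t,
    )


@dataclass
class RapidChangeResult:
    """Across-site-year weekly-share distribution and the span of weeks
    over which the median weekly share sums highest."""

    start_week: int
    end_week: int
    span_weeks: int
    weekly_summary: pd.DataFrame = field(repr=False)  # index week: p25, p50, p75, min, max

    def to_dict(self) -> dict:
        return {
            "start_week": self.start_week,
            "end_week": self.end_week,
            "span_weeks": self.span_weeks,
            "weekly_summary": {
                str(wk): {k: float(v) for k, v in row.items()}
                for wk, row in self.weekly_summary.iterrows()
            },
        }


def rapid_change_weeks(
    shares_by_site_year: Mapping[str, pd.Series] | Iterable[pd.Series],
    span_weeks: int = 4,
) -> RapidChangeResult:
    """Find the ``span_weeks`` consecutive weeks of most rapid change.

    Input: weekly share series (week-of-year → share of yearly total) for
    one or more site-years. Per week, 25/50/75 percentiles plus min and
    max are computed across site-years (weeks absent from a site-year
    count as share 0 for that site-year). The reported range is the
    contiguous span maximizing the summed median share; ties break to the
    earliest start.
    """
    if isinstance(shares_by_site_year, Mapping):
        series = {str(k): v for k, v in shares_by_site_year.items()}
    else:
        series = {f"sy{i}": s for i, s in enumerate(shares_by_site_year)}
    if not series:
        raise ValueError("at least one site-year of weekly shares required")
    wide = pd.DataFrame(series).fillna(0.0).sort_index()
    summary = pd.DataFrame(
        {
            "p25": wide.quantile(0.25, axis=1),
            "p50": wide.quantile(0.50, axis=1),
            "p75": wide.quantile(0.75, axis=1),
            "min": wide.min(axis=1),
            "max": wide.max(axis=1),
        }
    )
    weeks = summary.index.to_numpy()
    medians = summary["p50"].to_numpy()
    if len(weeks) < span_weeks:
        span_weeks = len(weeks)
    best_sum, best_i = -np.inf, 0
    for i in range(len(weeks) - span_weeks + 1):
        # only truly contiguous week runs qualify
        if weeks[i + span_weeks - 1] - weeks[i] != span_weeks - 1:
            continue
        s = medians[i : i + span_weeks].sum()
        if s > best_sum + 1e-15:
            best_sum, best_i = s, i
    return RapidChangeResult(
        start_week=int(weeks[best_i]),
        end_week=int(weeks[best_i + span_weeks - 1]),
        span_weeks=span_weeks,
        weekly_summary=summary,
    )


def rolling_edaphic(weather: WeatherSeries, window_days: int = 7) -> pd.DataFrame:
    """Trailing rolling means of soil temperature and rainfall per date.

    The window ends at each date (trailing); the first ``window_days − 1``
    days have no complete window and are NaN. Columns: ``soil_temp_roll``
    (requires ``t_soil_5cm``) and ``rain_roll`` (requires ``rainfall``);
    only present fields are rolled.
    """
    if window_days < 1:
        raise ValueError("window_days must be ≥ 1")
    df = weather.data.set_index("date")
    out = pd.DataFrame(index=df.index)
    if "t_soil_5cm" in df.columns:
        out["soil_temp_roll"] = df["t_soil_5cm"].rolling(window_days).mean()
    if "rainfall" in df.columns:
        out["rain_roll"] = df["rainfall"].rolling(window_days).mean()
    if out.empty or not out.columns.size:
        raise ValueError("weather lacks both t_soil_5cm and rainfall")
    return out


def summarize_edaphic(
    rollings: Sequence[pd.DataFrame],
    start,
    end,
) -> EdaphicSummary:
    """Summarize rolling edaphic series over a date range, across site-years.

    Each element of ``rollings`` is a :func:`rolling_edaphic` frame for
    one site-year. Per series, rolling values inside [start, end] are
    averaged; the summary reports the mean of those per-series means and
    the across-series population sd ("spread"). Errors if any series has
    no complete window inside the range.
    """
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    soil_means, rain_means = [], []
    for i, roll in enumerate(rollings):
        sub = roll[(roll.index >= start_ts) & (roll.index <= end_ts)]
        if "soil_temp_roll" in sub:
            vals = sub["soil_temp_roll"].dropna()
            if vals.empty:
                raise ValueError(f"series {i}: no complete soil-temp window in range")
            soil_means.append(float(vals.mean()))
        if "rain_roll" in sub:
            vals = sub["rain_roll"].dropna()
            if vals.empty:
                raise ValueError(f"series {i}: no complete rainfall window in range")
            rain_means.append(float(vals.mean()))
    if not soil_means or not rain_means:
        raise ValueError("need both soil temperature and rainfall rolling series")
    return EdaphicSummary(
        start=start_ts.date(),
        end=end_ts.date(),
        soil_temp_7d_mean=float(np.mean(soil_means)),
        soil_temp_spread=float(np.std(soil_means)),
        rainfall_7d_mean=float(np.mean(rain_means)),
        rainfall_spread=float(np.std(rain_means)),
    )


def day_night_means(
    readings: pd.DataFrame,
    day_hours: tuple[int, int] = (7, 19),
    window: tuple[_dt.date, _dt.date] | None = None,
) -> tuple[float, float]:
    """Mean day and night air temperature from sub-daily readings.

    "Day" is the fixed clock interval [day_hours[0], day_hours[1]) local
    time (default 07:00–19:00); night is the complement. ``readings``
    needs columns (timestamp, value) in its first two positions. Raises if
    the data carry no intra-day time information (daily-only weather).
    """
    frame = readings.iloc[:, :2].copy()
    frame.columns = ["timestamp", "value"]
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    if window is not None:
        lo = pd.Timestamp(window[0])
        hi = pd.Timestamp(window[1]) + pd.Timedelta(days=1)
        frame = frame[(frame["timestamp"] >= lo) & (frame["timestamp"] < hi)]
    if frame.empty:
        raise ValueError("no readings in the requested window")
    hours = frame["timestamp"].dt.hour
    if (hours == 0).all() and (frame["timestamp"].dt.minute == 0).all():
        raise ValueError("sub-daily data required for day/night means")
    is_day = (hours >= day_hours[0]) & (hours < day_hours[1])
    if not is_day.any() or is_day.all():
        raise ValueError("readings do not cover both day and night hours")
    return (
        float(frame.loc[is_day, "value"].mean()),
        float(frame.loc[~is_day, "value"].mean()),
    )
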