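"""Emergence-curve construction from dated seedling counts.

Field observations are destructive counts: every newly emerged seedling
inside a monitoring circle is recorded and removed, so each record is the
number of *new* seedlings since the previous visit. This module turns
those records into cumulative emergence curves aligned to thermal time
(yearly-cumulative fraction vs cooling degree days), extracts the
early-season (0–50 % of yearly total) portion used for Gompertz fitting,
and maps counts onto week-of-year shares for peak-timing analysis.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .thermal_time import ThermalTimeSeries, thermal_time_at_date

__all__ = [
    "EmergenceCurve",
    "build_curve",
    "early_season_subset",
    "weekly_shares",
    "read_emergence_csv",
    "write_emergence_csv",
    "write_curve_csv",
    "read_curve_csv",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["site_id", "plot_id", "date", "new_seedlings"]

WeekConvention = Literal["iso", "simple"]
Pooling = Literal["sum_plots", "per_plot"]

#: Observation gaps longer than this many days are treated as biweekly
#: visits whose count is split evenly across the two covered weeks.
BIWEEKLY_GAP_DAYS = 9


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"emergence records missing column(s) {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    counts = df["new_seedlings"]
    if (counts < 0).any():
        raise ValueError("new_seedlings must be non-negative")
    if not np.array_equal(counts, counts.astype(int)):
        raise ValueError("new_seedlings must be integer counts")
    df["new_seedlings"] = counts.astype(int)
    if df.duplicated(subset=["site_id", "plot_id", "date"]).any():
        raise ValueError("duplicate (site, plot, date) emergence records")
    return df


@dataclass
class EmergenceCurve:
    """Cumulative emergence for one site-year, aligned to thermal time.

    ``data`` columns: ``date`` (observation day), ``cdd`` (cumulative
    degree days at that day), ``cum_count`` (non-decreasing integer),
    ``cum_fraction`` (= cum_count / yearly_total; exactly 1 at the final
    point). ``plot_id`` is None for plot-pooled curves.
    """

    site_id: str
    season_year: int
    yearly_total: int
    data: pd.DataFrame = field(repr=False)
    plot_id: str | None = None

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        if df.empty:
            raise ValueError("emergence curve has no points")
        if (df["cum_count"].diff().dropna() < 0).any():
            raise ValueError("cum_count must be non-decreasing")
        if (df["cdd"].diff().dropna() < -1e-9).any():
            raise ValueError("cdd must be non-decreasing along the curve")
        if int(df["cum_count"].iloc[-1]) != self.yearly_total:
            raise ValueError("final cum_count must equal yearly_total")
        self.data = df

    @property
    def counts(self) -> pd.Series:
        """Per-observation new-seedling counts (first diff of cum_count)."""
        return self.data["cum_count"].diff().fillna(self.data["cum_count"].iloc[0]).astype(int)

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """(cdd, cum_fraction) arrays ready for model fitting."""
        return (
            self.data["cdd"].to_numpy(dtype=float),
            self.data["cum_fraction"].to_numpy(dtype=float),
        )


def build_curve(
    records: pd.DataFrame,
    tts: ThermalTimeSeries,
    season_year: int,
    pooling: Pooling = "sum_plots",
) -> EmergenceCurve | dict[str, EmergenceCurve]:
    """Accumulate dated counts into cumulative emergence curve(s).

    Records are restricted to ``season_year`` (seasons here are
    autumn-contained, so a calendar year is a season) and to the site of
    ``tts``; observation dates before the thermal-time anchor are dropped
    with a warning. With ``sum_plots`` the monitored plots are pooled into
    one curve; ``per_plot`` returns a dict keyed by plot_id.
    """
    df = _validate_records(records)
    df = df[df["site_id"].astype(str) == tts.site_id]
    df = df[df["date"].dt.year == season_year]
    anchor = pd.Timestamp(tts.anchor_date)
    before = df["date"] < anchor
    if before.any():
        logger.warning(
            "dropping %d observation(s) before anchor %s for site %s",
            int(before.sum()),
            tts.anchor_date,
            tts.site_id,
        )
        df = df[~before]
    if df.empty:
        raise ValueError(
            f"no emergence records for site {tts.site_id!r} in {season_year} at/after anchor"
        )

    if pooling == "per_plot":
        return {
            str(plot): _one_curve(grp, tts, season_year, plot_id=str(plot))
            for plot, grp in df.groupby("plot_id", sort=True)
        }
    if pooling != "sum_plots":
        raise ValueError(f"unknown pooling {pooling!r}")
    return _one_curve(df, tts, season_year, plot_id=None)


def _one_curve(
    df: pd.DataFrame, tts: ThermalTimeSeries, season_year: int, plot_id: str | None
) -> EmergenceCurve:
    daily = df.groupby("date", sort=True)["new_seedlings"].sum()
    total = int(daily.sum())
    if total == 0:
        who = f"plot {plot_id!r}" if plot_id else f"site {tts.site_id!r}"
        raise ValueError(f"no emergence observed for {who} in {season_year}")
    cum = daily.cumsum()
    data = pd.DataFrame(
        {
            "date": daily.index,
            "cdd": [thermal_time_at_date(tts, d) for d in daily.index],
            "cum_count": cum.to_numpy(dtype=int),
            "cum_fraction": cum.to_numpy(dtype=float) / total,
        }
    )
    return EmergenceCurve(
        site_id=tts.site_id,
        season_year=season_year,
        yearly_total=total,
        data=data,
        plot_id=plot_id,
    )


def early_season_subset(curve: EmergenceCurve, ceiling: float = 0.5) -> pd.DataFrame:
    """Points up to the early-season ceiling (default 0–50 % of yearly total).

    Keeps every point with ``cum_fraction ≤ ceiling``, plus the first
    point strictly exceeding it when no kept point reaches the ceiling
    exactly — so the fitted curve always sees the crossing. May return a
    single point.
    """
    if not (0 < ceiling <= 1):
        raise ValueError("ceiling must lie in (0, 1]")
    frac = curve.data["cum_fraction"].to_numpy()
    keep = frac <= ceiling
    crossing_seen = keep.any() and frac[keep].max() >= ceiling
    above = np.nonzero(~keep)[0]
    if not crossing_seen and len(above):
        keep[above[0]] = True
    return curve.data.loc[keep].reset_index(drop=True)


def _week_of_year(day: pd.Timestamp, convention: WeekConvention) -> int:
    if convention == "iso":
        return int(day.isocalendar().week)
    if convention == "simple":
        return int((day.dayofyear - 1) // 7 + 1)
    raise ValueError(f"unknown week convention {convention!r}")


def weekly_shares(
    curve: EmergenceCurve, week_convention: WeekConvention = "iso"
) -> pd.Series:
    """Share of the yearly total emerging in each week of the year.

    Each observation's new-seedling count is assigned to the week of its
    observation date. Biweekly visits (gap to the previous observation
    longer than ``BIWEEKLY_GAP_DAYS`` days) are split evenly between the
    observation week and the week seven days earlier, since the count
    covers both. Shares sum to 1.
    """
    dates = curve.data["date"]
    counts = curve.counts.to_numpy(dtype=float)
    gaps = dates.diff().dt.days.to_numpy()
    shares: dict[int, float] = {}
    for i, (day, count) in enumerate(zip(dates, counts)):
        if count == 0:
            continue
        gap = gaps[i]
        if not np.isnan(gap) and gap > BIWEEKLY_GAP_DAYS:
            halves = [(day, count / 2.0), (day - pd.Timedelta(days=7), count / 2.0)]
        else:
            halves = [(day, count)]
        for d, c in halves:
            wk = _week_of_year(d, week_convention)
            shares[wk] = shares.get(wk, 0.0) + c
    out = pd.Series(shares, dtype=float).sort_index() / curve.yearly_total
    out.index.name = "week"
    out.name = "share"
    return out


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_emergence_csv(path) -> pd.DataFrame:
    """Read the site_id,plot_id,date,new_seedlings records CSV."""
    df = pd.read_csv(path, parse_dates=["date"])
    return _validate_records(df)


def write_emergence_csv(records: pd.DataFrame, path) -> None:
    df = _validate_records(records)[RECORD_COLUMNS].copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def write_curve_csv(curve: EmergenceCurve, path) -> None:
    df = curve.data.copy()
    df.insert(0, "site_id", curve.site_id)
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write(
            f"# season_year={curve.season_year} yearly_total={curve.yearly_total} "
            f"plot_id={curve.plot_id or '-'}\n"
        )
        df.to_csv(fh, index=False, float_format="%.10g")


def read_curve_csv(path) -> EmergenceCurve:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("curve CSV missing metadata header line")
        meta = dict(tok.split("=", 1) for tok in first.lstrip("#").split())
        df = pd.read_csv(fh, parse_dates=["date"])
    plot = None if meta.get("plot_id", "-") == "-" else meta["plot_id"]
    return EmergenceCurve(
        site_id=str(df["site_id"].iloc[0]),
        season_year=int(meta["season_year"]),
        yearly_total=int(meta["yearly_total"]),
        data=df.drop(columns="site_id"),
        plot_id=plot,
    )
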