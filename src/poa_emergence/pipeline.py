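"""Config-driven end-to-end runs.

One call chains every stage: ingest (or simulate) weather and emergence
records → cooling-degree-day accumulation → cumulative emergence curves →
non-linear model fits → thermal-time benchmarks → peak windows, weekly
shares, rapid-change weeks and edaphic summaries → optional predictor
screening — and writes a machine-readable JSON report (validated against
the published schema) with CSV sidecars. Runs are stateless and
deterministic: the same config and seed produce a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import emergence as _emergence
from . import metrics as _metrics
from . import models as _models
from . import synthetic as _synthetic
from . import windows as _windows
from .thermal_time import (
    DEFAULT_BASE_TEMP,
    accumulate,
    date_at_thermal_time,
    read_weather_csv,
    summer_solstice,
    write_thermal_csv,
)

__all__ = ["RunConfig", "RunReport", "run", "load_config", "report_json_schema"]

logger = logging.getLogger(__name__)

SCHEMA_PATH = Path(__file__).parent / "schemas" / "run_report.schema.json"


class SimulationSpec(BaseModel):
    """Simulation source: thin, YAML-friendly view of SimulationConfig."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_sites: int = 1
    season_year: int = 2019
    seedbank_n: int = 10_000
    n_plots: int = 4
    true_model: dict = {"kind": "gompertz", "a": 0.485, "b": 12.141, "c": 0.081}
    temp: dict = {}
    rain: dict = {}

    def to_config(self) -> _synthetic.SimulationConfig:
        return _synthetic.SimulationConfig(
            seed=self.seed,
            n_sites=self.n_sites,
            season_year=self.season_year,
            seedbank_n=self.seedbank_n,
            n_plots=self.n_plots,
            true_model=_synthetic.TrueModel(**self.true_model),
            temp=_synthetic.TempModel(**self.temp),
            rain=_synthetic.RainModel(**self.rain),
        )


class RunConfig(BaseModel):
    """End-to-end run configuration: file inputs XOR a simulation."""

    model_config = ConfigDict(extra="forbid")

    weather_csv: Optional[str] = None
    emergence_csv: Optional[str] = None
    predictors_csv: Optional[str] = None
    response_csv: Optional[str] = None
    simulation: Optional[SimulationSpec] = None

    season_year: Optional[int] = None
    base_temp: float = DEFAULT_BASE_TEMP
    anchor_date: Optional[_dt.date] = None
    direction: Literal["below_base", "above_base"] = "below_base"
    temp_field: str = "t_air_mean"
    model_kinds: list[Literal["gompertz", "saturating_exp"]] = [
        "gompertz",
        "saturating_exp",
    ]
    early_season_ceiling: float = 0.5
    window_weeks: int = 4
    span_weeks: int = 4
    benchmark_targets: list[float] = [0.5, 0.75]
    screen_in_simulation: bool = True
    screen_response_mode: Literal["increments", "cumulative"] = "increments"
    plot: bool = False
    out_dir: str = "run_output"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        files = self.weather_csv is not None and self.emergence_csv is not None
        partial_files = (self.weather_csv is None) != (self.emergence_csv is None)
        if partial_files:
            raise ValueError("weather_csv and emergence_csv must be given together")
        if files and self.simulation is not None:
            raise ValueError("config must name files or a simulation, not both")
        if not files and self.simulation is None:
            raise ValueError("config must name either input files or a simulation")
        if files and self.season_year is None:
            raise ValueError("season_year is required with file inputs")
        return self


# --- report schema ---------------------------------------------------------


class FitReport(BaseModel):
    kind: str
    params: dict[str, float]
    metrics: dict[str, Optional[float]]
    n_points: int
    converged: bool
    early_season: bool
    benchmarks: dict[str, Optional[float]]
    benchmark_dates: dict[str, Optional[str]]


class PeakWindowReport(BaseModel):
    site_id: str
    season_year: int
    start_date: str
    end_date: str
    length_weeks: int
    share: float
    cdd_span: list[float]
    mean_air_temp: Optional[float] = None
    mean_soil_temp: Optional[float] = None
    total_rainfall: Optional[float] = None
    day_air_temp: Optional[float] = None
    night_air_temp: Optional[float] = None


class SiteYearReport(BaseModel):
    site_id: str
    season_year: int
    anchor_date: str
    yearly_total: int
    n_observations: int
    final_cdd: float
    fits: list[FitReport]
    peak_window: PeakWindowReport
    weekly_shares: dict[str, float]


class RapidChangeReport(BaseModel):
    start_week: int
    end_week: int
    span_weeks: int
    weekly_summary: dict[str, dict[str, float]]


class EdaphicReport(BaseModel):
    start: str
    end: str
    soil_temp_7d_mean: float
    soil_temp_spread: float
    rainfall_7d_mean: float
    rainfall_spread: float


class ScreenReport(BaseModel):
    response: str
    ranking: list[dict]


class RunReport(BaseModel):
    """Schema of the JSON report a run writes."""

    package: str
    config: dict
    seed: Optional[int]
    sites: list[SiteYearReport]
    rapid_change: Optional[RapidChangeReport]
    edaphic: Optional[EdaphicReport]
    screen: Optional[ScreenReport]


def report_json_schema() -> dict:
    return RunReport.model_json_schema()


# --- stages ----------------------------------------------------------------


def load_config(path) -> RunConfig:
    """Read a YAML run config."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def _stage(name: str):
    """Decorator attaching the stage name to any propagated error."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.3fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("ingest")
def _ingest(config: RunConfig):
    if config.simulation is not None:
        sim = config.simulation.to_config()
        weather = _synthetic.simulate_weather(sim)
        records = _synthetic.simulate_emergence(weather, sim)
        season_year = sim.season_year
        seed = sim.seed
        logger.info("simulated %d site(s), %d records", len(weather), len(records))
    else:
        weather = read_weather_csv(config.weather_csv)
        records = _emergence.read_emergence_csv(config.emergence_csv)
        season_year = int(config.season_year)  # validated present
        seed = None
        logger.info("read %d site(s), %d records", len(weather), len(records))
    return weather, records, season_year, seed


def _fit_site(config: RunConfig, curve, tts) -> list[FitReport]:
    fits = []
    for kind in config.model_kinds:
        early = kind == "gompertz"
        if early:
            pts = _emergence.early_season_subset(curve, config.early_season_ceiling)
            xy = (pts["cdd"].to_numpy(float), pts["cum_fraction"].to_numpy(float))
        else:
            xy = curve.points()
        fit = _models.fit(xy, kind)
        bench: dict[str, Optional[float]] = {}
        bench_dates: dict[str, Optional[str]] = {}
        for t in config.benchmark_targets:
            key = f"cdd_at_{round(t * 100)}"
            try:
                cdd = _models.invert(fit, t)
            except ValueError:
                bench[key], bench_dates[key] = None, None
                continue
            bench[key] = cdd
            try:
                bench_dates[key] = date_at_thermal_time(tts, cdd).isoformat()
            except ValueError:
                bench_dates[key] = None
        d = fit.to_dict()
        fits.append(
            FitReport(
                kind=d["kind"],
                params=d["params"],
                metrics=d["metrics"],
                n_points=d["n_points"],
                converged=d["converged"],
                early_season=early,
                benchmarks=bench,
                benchmark_dates=bench_dates,
            )
        )
    return fits


def _screen(config: RunConfig, seed: Optional[int], n_obs: int) -> Optional[ScreenReport]:
    if config.predictors_csv is not None and config.response_csv is not None:
        predictors = pd.read_csv(config.predictors_csv)
        response = pd.read_csv(config.response_csv).iloc[:, -1]
    elif config.simulation is not None and config.screen_in_simulation:
        predictors, response = _synthetic.simulate_predictors(
            seed=(seed or 0) + 1_000_003, n=max(n_obs, 50)
        )
    else:
        return None
    result = _metrics.pearson_screen(predictors, response)
    return ScreenReport(**result.to_dict())


def run(config: RunConfig, write: bool = True) -> dict:
    """Execute the full pipeline; return (and optionally write) the report.

    The report dict validates against the published JSON schema; with
    ``write=True`` it is saved as ``report.json`` in ``out_dir`` together
    with per-site thermal-time and curve CSVs (and figures when
    ``plot=True``).
    """
    weather, records, season_year, seed = _ingest(config)
    out_dir = Path(config.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)

    anchor = config.anchor_date or summer_solstice(season_year)
    site_reports: list[SiteYearReport] = []
    shares_by_site: dict[str, pd.Series] = {}
    rollings = []
    curves = {}

    for site_id in sorted(weather):
        ws = weather[site_id]
        tts = _stage("thermal_time")(accumulate)(
            ws,
            base_temp=config.base_temp,
            anchor_date=anchor,
            direction=config.direction,
            temp_field=config.temp_field,
        )
        curve = _stage("curves")(_emergence.build_curve)(records, tts, season_year)
        curves[site_id] = (curve, tts)
        fits = _stage("fit")(_fit_site)(config, curve, tts)
        peak = _stage("windows")(_windows.peak_window)(
            curve, ws, weeks=config.window_weeks
        )
        shares = _emergence.weekly_shares(curve)
        shares_by_site[f"{site_id}-{season_year}"] = shares
        try:
            rollings.append(_windows.rolling_edaphic(ws))
        except ValueError:
            pass
        site_reports.append(
            SiteYearReport(
                site_id=site_id,
                season_year=season_year,
                anchor_date=tts.anchor_date.isoformat(),
                yearly_total=curve.yearly_total,
                n_observations=len(curve.data),
                final_cdd=tts.final_cumulative,
                fits=fits,
                peak_window=PeakWindowReport(**peak.to_dict()),
                weekly_shares={str(k): float(v) for k, v in shares.items()},
            )
        )

    rapid = _stage("rapid_change")(_windows.rapid_change_weeks)(
        shares_by_site, span_weeks=config.span_weeks
    )
    edaphic = None
    if rollings:
        try:
            start = _dt.date.fromisocalendar(season_year, rapid.start_week, 1)
            end = _dt.date.fromisocalendar(season_year, rapid.end_week, 7)
            edaphic = _windows.summarize_edaphic(rollings, start, end)
        except ValueError:
            logger.warning("edaphic summary skipped: incomplete rolling windows")

    n_obs = sum(sr.n_observations for sr in site_reports)
    screen = _stage("screen")(_screen)(config, seed, n_obs)

    report_model = RunReport(
        package="poa_emergence",
        config=json.loads(config.model_dump_json()),
        seed=seed,
        sites=site_reports,
        rapid_change=RapidChangeReport(**rapid.to_dict()),
        edaphic=EdaphicReport(**edaphic.to_dict()) if edaphic else None,
        screen=screen,
    )
    report = report_model.model_dump()

    if write:
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        for site_id, (curve, tts) in curves.items():
            _emergence.write_curve_csv(curve, out_dir / f"curve_{site_id}.csv")
            write_thermal_csv(tts, out_dir / f"thermal_{site_id}.csv")
        rapid.weekly_summary.to_csv(out_dir / "weekly_percentiles.csv")
        if config.plot:
            for site_id, (curve, tts) in curves.items():
                _plot_site(curve, site_reports, out_dir / f"curve_{site_id}.png")
    return report


def _plot_site(curve, site_reports, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    x, y = curve.points()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, y, "o", label="observed", color="tab:green")
    grid = np.linspace(0, x.max(), 200)
    for sr in site_reports:
        if sr.site_id != curve.site_id:
            continue
        for f in sr.fits:
            p = f.params
            ax.plot(
                grid,
                _models.evaluate(f.kind, grid, p["a"], p["b"], p["c"]),
                label=f.kind,
            )
    ax.set_xlabel("cooling degree days (CDD$_{21C}$)")
    ax.set_ylabel("cumulative emergence fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
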