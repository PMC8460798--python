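"""Peak-window detection, rapid-change weeks, edaphic summaries."""

import numpy as np
import pandas as pd
import pytest

import poa_emergence as pe

from conftest import make_curve, make_weather


def weekly_curve(counts, start="2019-09-02"):
    dates = pd.date_range(start, periods=len(counts), freq="7D")
    return make_curve(dates, counts)


class TestPeakWindow:
    def test_uniform_emergence_earliest_window(self):
        curve = weekly_curve([5] * 10)
        pw = pe.peak_window(curve, weeks=4)
        assert pw.share == pytest.approx(0.4)
        assert pw.start_date == curve.data["date"].iloc[0].date()

    def test_single_burst_captured(self):
        curve = weekly_curve([0, 0, 50, 0, 0, 0])
        pw = pe.peak_window(curve, weeks=4)
        assert pw.share == pytest.approx(1.0)
        assert pw.start_date <= curve.data["date"].iloc[2].date() <= pw.end_date

    def test_hand_scanned_window(self):
        # weekly counts [1,5,5,5,5,1]: best 4-week window covers weeks 2-5
        curve = weekly_curve([1, 5, 5, 5, 5, 1])
        pw = pe.peak_window(curve, weeks=4)
        assert pw.share == pytest.approx(20 / 22)
        assert pw.start_date == curve.data["date"].iloc[1].date()

    def test_curve_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            pe.peak_window(weekly_curve([1, 2, 3]), weeks=4)

    def test_weather_summaries(self):
        curve = weekly_curve([1, 5, 5, 5, 5, 1])
        n = 120
        weather = make_weather(
            [18.0] * n,
            start="2019-08-20",
            rainfall=[2.0] * n,
            soil=[16.0] * n,
        )
        pw = pe.peak_window(curve, weather, weeks=4)
        assert pw.mean_air_temp == pytest.approx(18.0)
        assert pw.mean_soil_temp == pytest.approx(16.0)
        assert pw.total_rainfall == pytest.approx(2.0 * 28)
        assert pw.day_air_temp is None  # daily weather carries no day/night split

    def test_exhaustive_scan_oracle_equivalence(self):
        """Detected share equals the brute-force maximum over all starts."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(6, 15)
            counts = rng.integers(0, 20, n)
            counts[rng.integers(0, n)] += 1  # guarantee a nonzero total
            curve = weekly_curve(list(counts))
            pw = pe.peak_window(curve, weeks=4)
            dates = list(curve.data["date"])
            total = counts.sum()
            best = max(
                sum(
                    int(c)
                    for d2, c in zip(dates, counts)
                    if d0 <= d2 < d0 + pd.Timedelta(days=28)
                )
                / total
                for d0 in dates
            )
            assert pw.share == pytest.approx(best)


class TestRapidChangeWeeks:
    def test_single_site_year_medians_equal_shares(self):
        shares = pd.Series({38: 0.1, 39: 0.2, 40: 0.4, 41: 0.3})
        res = pe.rapid_change_weeks({"a-2019": shares}, span_weeks=2)
        np.testing.assert_allclose(res.weekly_summary["p50"], shares.values)
        assert (res.start_week, res.end_week) == (40, 41)

    def test_identical_site_years_collapse(self):
        shares = pd.Series({40: 0.6, 41: 0.4})
        res = pe.rapid_change_weeks({"a": shares, "b": shares}, span_weeks=2)
        row = res.weekly_summary.loc[40]
        assert row["p25"] == row["p50"] == row["p75"] == row["min"] == row["max"] == 0.6

    def test_constructed_peak_detected(self):
        """Three site-years peaked over weeks 40-43 yield that range."""
        rng = np.random.default_rng(9)
        site_years = {}
        for i in range(3):
            weeks = np.arange(36, 48)
            shares = np.exp(-0.5 * ((weeks - 41.5) / 1.2) ** 2)
            shares += rng.uniform(0, 0.02, len(weeks))
            site_years[f"s{i}"] = pd.Series(shares / shares.sum(), index=weeks)
        res = pe.rapid_change_weeks(site_years, span_weeks=4)
        assert (res.start_week, res.end_week) == (40, 43)

    def test_permutation_of_site_years_invariant(self):
        a = pd.Series({40: 0.5, 41: 0.3, 42: 0.2})
        b = pd.Series({40: 0.2, 41: 0.5, 42: 0.3})
        r1 = pe.rapid_change_weeks({"x": a, "y": b}, span_weeks=2)
        r2 = pe.rapid_change_weeks({"x": b, "y": a}, span_weeks=2)
        pd.testing.assert_frame_equal(r1.weekly_summary, r2.weekly_summary)


class TestRollingEdaphic:
    def test_constant_series(self):
        w = make_weather([20.0] * 20, soil=[18.0] * 20, rainfall=[1.0] * 20)
        roll = pe.rolling_edaphic(w)
        assert np.allclose(roll["soil_temp_roll"].dropna(), 18.0)

    def test_single_rain_event(self):
        rain = [0, 0, 0, 0, 0, 0, 7.0]
        w = make_weather([20.0] * 7, soil=[18.0] * 7, rainfall=rain)
        roll = pe.rolling_edaphic(w)
        assert roll["rain_roll"].iloc[-1] == pytest.approx(1.0)

    def test_arithmetic_sequence_mean(self):
        w = make_weather([20.0] * 7, soil=list(range(10, 17)))
        roll = pe.rolling_edaphic(w)
        assert roll["soil_temp_roll"].iloc[-1] == pytest.approx(13.0)

    def test_commutes_with_affine_rescaling(self):
        soil = list(np.linspace(8, 20, 30))
        w1 = make_weather([20.0] * 30, soil=soil)
        w2 = make_weather([20.0] * 30, soil=[2 * s + 1 for s in soil])
        r1 = pe.rolling_edaphic(w1)["soil_temp_roll"]
        r2 = pe.rolling_edaphic(w2)["soil_temp_roll"]
        np.testing.assert_allclose(r2.dropna(), 2 * r1.dropna() + 1)

    def test_summary_across_site_years(self):
        w1 = make_weather([20.0] * 30, soil=[18.0] * 30, rainfall=[1.0] * 30)
        w2 = make_weather([20.0] * 30, soil=[20.0] * 30, rainfall=[3.0] * 30)
        rolls = [pe.rolling_edaphic(w) for w in (w1, w2)]
        summ = pe.summarize_edaphic(rolls, "2019-07-01", "2019-07-10")
        assert summ.soil_temp_7d_mean == pytest.approx(19.0)
        assert summ.soil_temp_spread == pytest.approx(1.0)
        assert summ.rainfall_7d_mean == pytest.approx(2.0)

    def test_no_complete_window_errors(self):
        w = make_weather([20.0] * 30, soil=[18.0] * 30, rainfall=[1.0] * 30)
        roll = pe.rolling_edaphic(w)
        with pytest.raises(ValueError, match="no complete"):
            pe.summarize_edaphic([roll], "2019-06-21", "2019-06-23")


class TestDayNightMeans:
    @staticmethod
    def hourly_frame(fn, days=2):
        times = pd.date_range("2019-10-01", periods=24 * days, freq="h")
        return pd.DataFrame({"timestamp": times, "value": [fn(t) for t in times]})

    def test_constant(self):
        frame = self.hourly_frame(lambda t: 15.0)
        assert pe.day_night_means(frame) == (15.0, 15.0)

    def test_step_profile_by_construction(self):
        frame = self.hourly_frame(lambda t: 20.0 if 7 <= t.hour < 19 else 10.0)
        day, night = pe.day_night_means(frame)
        assert (day, night) == (20.0, 10.0)

    def test_sinusoidal_cycle_orders_day_above_night(self):
        # amplitude-5 diurnal cycle about 15 °C peaking at 14:00
        frame = self.hourly_frame(
            lambda t: 15.0 + 5.0 * np.cos(2 * np.pi * (t.hour - 14) / 24)
        )
        day, night = pe.day_night_means(frame)
        assert day > 15.0 > night
        # numeric-integration oracle over the same clock split
        hours = np.arange(24)
        temps = 15.0 + 5.0 * np.cos(2 * np.pi * (hours - 14) / 24)
        mask = (hours >= 7) & (hours < 19)
        assert day == pytest.approx(temps[mask].mean())
        assert night == pytest.approx(temps[~mask].mean())

    def test_daily_only_data_rejected(self):
        times = pd.date_range("2019-10-01", periods=5, freq="D")
        frame = pd.DataFrame({"timestamp": times, "value": 15.0})
        with pytest.raises(ValueError, match="sub-daily"):
            pe.day_night_means(frame)
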