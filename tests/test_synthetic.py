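"""Synthetic-data generator: determinism, construction, statistics."""

import numpy as np
import pandas as pd
import pytest

import poa_emergence as pe
from poa_emergence.synthetic import CadenceBlock, observation_dates

WEEKLY = (CadenceBlock((1, 1), (12, 31), 7),)


class TestWeather:
    def test_same_seed_identical(self, sim_config):
        w1 = pe.simulate_weather(sim_config)["site01"]
        w2 = pe.simulate_weather(sim_config)["site01"]
        pd.testing.assert_frame_equal(w1.data, w2.data)

    def test_different_seed_differs(self, sim_config):
        w2 = pe.simulate_weather(sim_config.replace(seed=sim_config.seed + 1))["site01"]
        w1 = pe.simulate_weather(sim_config)["site01"]
        assert not np.allclose(w1.data["t_air_mean"], w2.data["t_air_mean"])

    def test_zero_noise_is_exact_cosine(self):
        cfg = pe.SimulationConfig(seed=0, temp=pe.TempModel(noise_sd=0.0))
        w = pe.simulate_weather(cfg)["site01"]
        tm = cfg.temp
        on_phase = w.data[w.data["date"].dt.dayofyear == tm.phase_doy]
        assert on_phase["t_air_mean"].iloc[0] == pytest.approx(
            tm.annual_mean + tm.annual_amplitude
        )
        doy = w.data["date"].dt.dayofyear.to_numpy(dtype=float)
        expected = tm.annual_mean + tm.annual_amplitude * np.cos(
            2 * np.pi * (doy - tm.phase_doy) / 365.0
        )
        np.testing.assert_allclose(w.data["t_air_mean"], expected)

    def test_wet_day_frequency(self):
        # ~10,000 simulated days: empirical wet frequency within ±0.01
        cfg = pe.SimulationConfig(seed=3, n_sites=28)
        weather = pe.simulate_weather(cfg)
        rain = np.concatenate([w.data["rainfall"].to_numpy() for w in weather.values()])
        assert len(rain) >= 10_000
        assert (rain > 0).mean() == pytest.approx(cfg.rain.wet_prob, abs=0.01)

    def test_weather_passes_its_own_validation(self, sim_weather):
        df = sim_weather.data
        assert (df["rainfall"] >= 0).all()
        assert df["soil_moisture"].between(0, 1).all()
        assert (df["t_air_min"] <= df["t_air_mean"]).all()
        assert (df["t_air_mean"] <= df["t_air_max"]).all()


class TestEmergence:
    def test_season_total_near_asymptote(self):
        cfg = pe.SimulationConfig(seed=7, seedbank_n=1000, cadence=WEEKLY)
        weather = pe.simulate_weather(cfg)
        records = pe.simulate_emergence(weather, cfg)
        total = records["new_seedlings"].sum()
        tts = pe.accumulate(weather["site01"], anchor_date=cfg.anchor_date)
        obs = [d for d in observation_dates(cfg.season_year, WEEKLY) if d >= cfg.anchor_date]
        f_end = float(cfg.true_model.fraction(tts.thermal_time_at(obs[-1])))
        expected = 1000 * f_end
        sd = np.sqrt(1000 * f_end * (1 - f_end))
        assert abs(total - expected) <= 3 * sd

    def test_no_counts_while_truth_is_flat(self):
        # noiseless warm summer: F stays at 0 until cooling starts, so
        # every pre-September observation interval yields zero seedlings
        cfg = pe.SimulationConfig(seed=1, temp=pe.TempModel(noise_sd=0.0))
        weather = pe.simulate_weather(cfg)
        records = pe.simulate_emergence(weather, cfg)
        early = records[records["date"] < "2019-09-01"]
        assert (early["new_seedlings"] == 0).all()

    def test_deterministic_records(self, sim_config, sim_weather):
        r1 = pe.simulate_emergence(sim_weather, sim_config)
        r2 = pe.simulate_emergence(sim_weather, sim_config)
        pd.testing.assert_frame_equal(r1, r2)

    def test_cumulative_conservation(self, sim_curve):
        assert (sim_curve.data["cum_count"].diff().dropna() >= 0).all()
        assert sim_curve.data["cum_count"].iloc[-1] == sim_curve.yearly_total
        assert sim_curve.data["cum_fraction"].iloc[-1] == 1.0

    def test_seedbank_scale_recovery_at_default_n(self):
        """One seeded instance: fit on counts/seedbank recovers the truth
        within 5% at N = 10,000."""
        cfg = pe.SimulationConfig(seed=20, cadence=WEEKLY)
        weather = pe.simulate_weather(cfg)
        records = pe.simulate_emergence(weather, cfg)
        tts = pe.accumulate(weather["site01"], anchor_date=cfg.anchor_date)
        curve = pe.build_curve(records, tts, cfg.season_year)
        frac = curve.data["cum_count"].to_numpy() / cfg.seedbank_n
        fit = pe.fit((curve.data["cdd"].to_numpy(), frac), "gompertz")
        np.testing.assert_allclose(fit.params, cfg.true_model.params, rtol=0.05)

    def test_recovery_error_shrinks_with_seedbank(self):
        """Parameter error scales roughly like N^(-1/2): two decades of
        seedbank size should shrink the rate-parameter error ~10-fold."""

        def rms_c_error(n, reps=12):
            cfg = pe.SimulationConfig(seed=5, seedbank_n=n, cadence=WEEKLY)
            weather = pe.simulate_weather(cfg)
            tts = pe.accumulate(weather["site01"], anchor_date=cfg.anchor_date)
            errs = []
            for r in range(reps):
                cfg_r = cfg.replace(seed=1000 + r)
                records = pe.simulate_emergence(weather, cfg_r)
                curve = pe.build_curve(records, tts, cfg.season_year)
                frac = curve.data["cum_count"].to_numpy() / n
                fit = pe.fit((curve.data["cdd"].to_numpy(), frac), "gompertz")
                errs.append((fit.c - cfg.true_model.c) / cfg.true_model.c)
            return float(np.sqrt(np.mean(np.square(errs))))

        small, large = rms_c_error(1_000), rms_c_error(100_000)
        ratio = small / large
        assert 3.0 < ratio < 33.0  # sqrt(100) = 10 with Monte-Carlo slack


class TestPredictors:
    def test_perfect_correlation_ranked_first(self):
        preds, resp = pe.simulate_predictors(seed=0, n=50, k=5, target_r=1.0)
        result = pe.pearson_screen(preds, resp)
        assert result.best == "cdd_accumulation_change"
        assert result.r_of(result.best) == pytest.approx(1.0)

    def test_zero_correlation_shrinks_with_n(self):
        preds, resp = pe.simulate_predictors(seed=0, n=5000, k=1, target_r=0.0)
        result = pe.pearson_screen(preds, resp)
        assert abs(result.r_of("cdd_accumulation_change")) < 0.05

    def test_designated_predictor_usually_ranked_first(self):
        """target_r = 0.9 vs 24 noise predictors: ranked first in ≥ 95%
        of 500 seeded replicates (n = 200 samples each)."""
        wins = 0
        for rep in range(500):
            preds, resp = pe.simulate_predictors(seed=rep, n=200, k=25, target_r=0.9)
            if pe.pearson_screen(preds, resp).best == "cdd_accumulation_change":
                wins += 1
        assert wins >= 475

    def test_invalid_target_r(self):
        with pytest.raises(ValueError):
            pe.simulate_predictors(seed=0, n=10, target_r=1.5)


class TestCadence:
    def test_study_schedule_blocks(self):
        dates = observation_dates(2019)
        dates = pd.to_datetime(dates)
        spring = dates[(dates >= "2019-01-01") & (dates <= "2019-05-31")]
        summer = dates[(dates >= "2019-06-01") & (dates <= "2019-08-31")]
        autumn = dates[(dates >= "2019-09-01") & (dates <= "2019-12-31")]
        assert (spring.to_series().diff().dropna().dt.days == 7).all()
        assert (summer.to_series().diff().dropna().dt.days == 14).all()
        assert (autumn.to_series().diff().dropna().dt.days == 7).all()

    def test_schedule_outside_weather_span_errors(self, sim_config):
        cfg = sim_config
        weather = pe.simulate_weather(cfg)["site01"]
        truncated = pe.WeatherSeries("site01", weather.data.iloc[:200])
        with pytest.raises(ValueError, match="outside weather span"):
            pe.simulate_emergence(truncated, cfg)
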