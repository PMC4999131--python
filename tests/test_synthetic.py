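"""The weather/event/yield generator: physical invariants and known truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from riceclim.events import CultivarStageProfile
from riceclim.synthetic import (DriverTerm, GroundTruthResponse,
                                WeatherGenParams, assign_yields,
                                calibrate_noise_sd, generate_cropping_events,
                                generate_daily_weather,
                                generate_regime_mixture, ground_truth_yield,
                                inject_missingness, signal_yield)

CULTIVARS = [CultivarStageProfile("A", 55, 36, 35),
             CultivarStageProfile("B", 58, 35, 33)]


class TestDailyWeather:
    def test_physical_invariants_hold_every_day(self, weather_10y):
        w = weather_10y
        assert (w["TM"] < w["TX"]).all()
        assert w["P"].ge(0).all()
        assert w["RH"].between(0, 100).all()
        assert (w["SR"] > 0).all()
        assert w.notna().all().all()

    def test_same_seed_is_bit_identical(self, default_params):
        a = generate_daily_weather(default_params, "2010-01-01", 400)
        b = generate_daily_weather(default_params, "2010-01-01", 400)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_degenerate_case_is_the_pure_harmonic(self):
        p = WeatherGenParams(tx_noise_sd=0.0, ar1_coef=0.0,
                             precip_wet_prob=0.0, dr_sd=0.0, dr_tx_coef=0.0,
                             rh_noise_sd=0.0, sr_noise_sd=0.0, seed=1)
        w = generate_daily_weather(p, "2010-01-01", 730)
        doy = w.index.dayofyear.to_numpy(dtype=float)
        harmonic = p.tx_mean + p.tx_seasonal_amp * np.cos(
            2 * np.pi * (doy - p.tx_seasonal_phase) / 365.25)
        np.testing.assert_allclose(w["TX"].to_numpy(), harmonic)
        assert (w["P"] == 0).all()
        assert (w["TX"] - w["TM"]).to_numpy() == pytest.approx(p.dr_mean)

    def test_long_run_moments_match_generating_values(self, default_params,
                                                      weather_10y):
        p, w = default_params, weather_10y
        assert abs(w["TX"].mean() - p.tx_mean) < 0.5
        doy = w.index.dayofyear.to_numpy(dtype=float)
        harmonic = p.tx_mean + p.tx_seasonal_amp * np.cos(
            2 * np.pi * (doy - p.tx_seasonal_phase) / 365.25)
        anom = w["TX"].to_numpy() - harmonic
        lag1 = np.corrcoef(anom[:-1], anom[1:])[0, 1]
        assert abs(lag1 - p.ar1_coef) < 0.05

    @pytest.mark.parametrize("field,value", [
        ("ar1_coef", 1.2), ("dr_ar1", -1.0), ("precip_wet_prob", 1.0),
        ("tx_mean", float("nan")),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            WeatherGenParams(**{field: value})


class TestCroppingEvents:
    def test_fixed_cycle_length(self, weather_2y):
        ev = generate_cropping_events(
            weather_2y, 1, CULTIVARS, (weather_2y.index[5], weather_2y.index[60]),
            cycle_days_mean=126, cycle_days_sd=0, seed=3)
        assert (ev["harvest_date"] - ev["sowing_date"]).dt.days.iloc[0] == 126

    def test_all_harvests_inside_weather_coverage(self, weather_2y):
        ev = generate_cropping_events(
            weather_2y, 500, CULTIVARS,
            (weather_2y.index[5], weather_2y.index[360]), seed=3)
        assert (ev["harvest_date"] <= weather_2y.index[-1]).all()
        assert (ev["sowing_date"] >= weather_2y.index[0]).all()
        cycles = (ev["harvest_date"] - ev["sowing_date"]).dt.days
        assert cycles.between(100, 160).all()

    def test_cultivar_proportions_honored(self, weather_2y):
        ev = generate_cropping_events(
            weather_2y, 2000, CULTIVARS,
            (weather_2y.index[5], weather_2y.index[360]), seed=4,
            cultivar_probs=[0.7, 0.3])
        frac = (ev["cultivar"] == "A").mean()
        assert abs(frac - 0.7) < 0.03

    def test_window_overflow_rejected(self, weather_2y):
        with pytest.raises(ValueError, match="coverage"):
            generate_cropping_events(
                weather_2y, 5, CULTIVARS,
                (weather_2y.index[5], weather_2y.index[-1]), seed=3)


class TestGroundTruth:
    def _row(self, tm_rep=22.7, sr_rip=0.0, cultivar="A"):
        row = {"Cultivar": cultivar, "TM_Avg_REP": tm_rep,
               "SR_Accu_RIP": sr_rip}
        return pd.Series(row)

    def test_yield_is_base_without_drivers_or_noise(self):
        resp = GroundTruthResponse(base_yield=6000.0)
        assert ground_truth_yield(self._row(), resp) == 6000.0

    def test_hinge_arithmetic_at_and_above_breakpoint(self):
        resp = GroundTruthResponse(
            base_yield=6000.0,
            driver_terms=(DriverTerm("TM_Avg_REP", "hinge", -300.0,
                                     breakpoint=22.7),))
        at = ground_truth_yield(self._row(tm_rep=22.7), resp)
        above = ground_truth_yield(self._row(tm_rep=24.7), resp)
        assert at == 6000.0
        assert above == pytest.approx(6000.0 - 600.0)

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError, match="unknown indicator"):
            DriverTerm("not_a_real_indicator", "linear", 1.0)

    def test_noise_free_yields_recompute_exactly(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "Cultivar": rng.choice(["A", "B"], 1000),
            "TM_Avg_REP": rng.normal(23.0, 1.0, 1000),
            "SR_Accu_RIP": rng.normal(14000, 900, 1000),
        })
        resp = GroundTruthResponse(
            base_yield=6000.0, cultivar_effects={"A": 150.0, "B": -80.0},
            driver_terms=(
                DriverTerm("TM_Avg_REP", "hinge", -300.0, breakpoint=22.7),
                DriverTerm("SR_Accu_RIP", "linear", 0.3),
            ), noise_sd=0.0)
        out = assign_yields(table, resp, seed=1)
        recomputed = np.array([max(signal_yield(r, resp), resp.yield_floor)
                               for _, r in table.iterrows()])
        np.testing.assert_array_equal(out["Yield"].to_numpy(), recomputed)

    def test_noise_calibration_hits_target_r2(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({"Cultivar": "A",
                              "SR_Accu_RIP": rng.normal(14000, 900, 4000)})
        resp0 = GroundTruthResponse(
            driver_terms=(DriverTerm("SR_Accu_RIP", "linear", 0.3),))
        sd = calibrate_noise_sd(table, resp0, 0.4)
        out = assign_yields(table, dataclasses.replace(resp0, noise_sd=sd),
                            seed=2)
        sig = 0.3 * table["SR_Accu_RIP"]
        r2 = np.corrcoef(sig, out["Yield"])[0, 1] ** 2
        assert abs(r2 - 0.4) < 0.05


class TestMissingness:
    def test_rate_zero_changes_nothing(self, weather_2y):
        out, mask = inject_missingness(weather_2y, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, weather_2y)
        assert not mask.any().any()

    def test_missing_fraction_near_rate(self, weather_10y):
        out, mask = inject_missingness(weather_10y, 0.1, seed=2)
        for c in out.columns:
            assert abs(out[c].isna().mean() - 0.1) < 0.02

    def test_mask_and_observed_partition_the_series(self, weather_2y):
        out, mask = inject_missingness(weather_2y, 0.2, seed=3)
        assert out[mask].isna().all().all()
        pd.testing.assert_frame_equal(out[~mask], weather_2y[~mask])


class TestRegimeMixture:
    def test_counts_and_labels_honored(self):
        p1 = WeatherGenParams()
        p2 = WeatherGenParams(tx_mean=p1.tx_mean + 4.0)
        bundles, labels, events = generate_regime_mixture(2, [p1, p2],
                                                          [7, 11], seed=5)
        assert len(bundles) == 18
        assert list(np.bincount(labels)) == [7, 11]
        assert set(events["regime"]) == {0, 1}

    def test_identical_regimes_warn(self):
        p = WeatherGenParams()
        with pytest.warns(UserWarning, match="identical regime"):
            generate_regime_mixture(2, [p, p], 3, seed=5)

    def test_single_regime_warns_and_labels_constant(self):
        with pytest.warns(UserWarning, match="single regime"):
            _, labels, _ = generate_regime_mixture(1, [WeatherGenParams()],
                                                   4, seed=5)
        assert set(labels) == {0}
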