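"""Station screening, hourly aggregation, daily QC, merging, solar radiation."""

import math

import numpy as np
import pandas as pd
import pytest

from riceclim import solar
from riceclim.weather import (NoEligibleStationError, QCLimits, StationMeta,
                              aggregate_hourly_to_daily, derive_ta_dr,
                              haversine_km, merge_station_series, qc_daily,
                              select_stations)


class TestSelectStations:
    CROP = dict(crop_lat=3.9, crop_lon=-75.0, crop_alt_m=300.0)

    def test_station_at_crop_location_retained_with_zero_distance(self):
        s = StationMeta("here", 3.9, -75.0, 300.0)
        out = select_stations([s], **self.CROP)
        assert out[0][0] is s and out[0][1] == pytest.approx(0.0)

    def test_station_11km_away_excluded_at_default_threshold(self):
        # ~0.1 deg latitude ~= 11.1 km
        far = StationMeta("far", 4.0, -75.0, 300.0)
        with pytest.raises(NoEligibleStationError):
            select_stations([far], **self.CROP)

    def test_altitude_tolerance_is_inclusive(self):
        ok = StationMeta("a", 3.91, -75.0, 350.0)
        bad = StationMeta("b", 3.91, -75.0, 351.0)
        out = select_stations([ok, bad], **self.CROP)
        assert [s.station_id for s, _ in out] == ["a"]

    def test_haversine_against_hand_computation(self):
        # spherical law of cosines at a modest separation
        lat1, lon1, lat2, lon2 = 3.9, -75.0, 4.4, -74.5
        d_hand = 6371.0088 * math.acos(
            math.sin(math.radians(lat1)) * math.sin(math.radians(lat2))
            + math.cos(math.radians(lat1)) * math.cos(math.radians(lat2))
            * math.cos(math.radians(lon2 - lon1)))
        assert abs(haversine_km(lat1, lon1, lat2, lon2) - d_hand) < 0.1


def _hourly_day(day: str, temps, precip=0.0, rh=80.0, sr=20.0):
    ts = pd.date_range(day, periods=len(temps), freq="h")
    return pd.DataFrame({"timestamp": ts, "temp": temps,
                         "precip": precip, "rh": rh, "sr": sr})


class TestHourlyAggregation:
    def test_full_day_extremes_and_sums(self):
        df = _hourly_day("2020-01-01", list(range(20, 28)) * 3, precip=0.5)
        out = aggregate_hourly_to_daily(df)
        assert out.loc["2020-01-01", "TX"] == 27
        assert out.loc["2020-01-01", "TM"] == 20
        assert out.loc["2020-01-01", "P"] == pytest.approx(12.0)

    def test_eighty_percent_rule_is_strict(self):
        # 19/24 hours ~= 0.79 -> day missing; 20 hours -> present
        d19 = _hourly_day("2020-01-01", [25.0] * 19)
        d20 = _hourly_day("2020-01-02", [25.0] * 20)
        out = aggregate_hourly_to_daily(pd.concat([d19, d20]))
        assert np.isnan(out.loc["2020-01-01", "TX"])
        assert out.loc["2020-01-02", "TX"] == 25.0

    def test_duplicate_timestamps_rejected_naming_the_day(self):
        df = _hourly_day("2020-03-05", [25.0] * 24)
        with pytest.raises(ValueError, match="2020-03-05"):
            aggregate_hourly_to_daily(pd.concat([df, df.iloc[:1]]))

    def test_matches_brute_force_daily_loop(self, rng):
        n_days = 30
        ts = pd.date_range("2021-06-01", periods=n_days * 24, freq="h")
        df = pd.DataFrame({
            "timestamp": ts,
            "temp": rng.normal(27, 3, len(ts)),
            "precip": rng.exponential(0.3, len(ts)),
            "rh": rng.uniform(40, 100, len(ts)),
            "sr": rng.uniform(0, 60, len(ts)),
        })
        df.loc[rng.random(len(df)) < 0.15, ["temp", "precip", "rh", "sr"]] = np.nan
        out = aggregate_hourly_to_daily(df)
        for day, grp in df.groupby(df["timestamp"].dt.normalize()):
            for col, var, how in (("temp", "TX", np.nanmax),
                                  ("temp", "TM", np.nanmin),
                                  ("precip", "P", np.nansum),
                                  ("rh", "RH", np.nanmean),
                                  ("sr", "SR", np.nansum)):
                vals = grp[col].to_numpy()
                expected = (how(vals) if np.isfinite(vals).sum() > 0.8 * 24
                            else np.nan)
                got = out.loc[day, var]
                assert (np.isnan(got) and np.isnan(expected)) or \
                    got == pytest.approx(expected)


class TestQC:
    def _series(self, **overrides):
        idx = pd.date_range("2020-01-01", periods=30)
        base = pd.DataFrame({"TX": 32.0 + np.linspace(0, 1, 30),
                             "TM": 22.0 + np.linspace(0, 1, 30),
                             "P": 2.0, "RH": 80.0 + np.linspace(0, 5, 30),
                             "SR": 420.0}, index=idx)
        for k, (i, v) in overrides.items():
            base.iloc[i, base.columns.get_loc(k)] = v
        return base

    def test_out_of_range_tx_flagged_and_blanked(self):
        out, rep = qc_daily(self._series(TX=(3, 50.0)))
        assert rep.range_violations["TX"] == 1
        assert np.isnan(out["TX"].iloc[3])

    def test_inverted_temperatures_blank_both(self):
        s = self._series()
        s.iloc[5, s.columns.get_loc("TM")] = 35.0  # above TX range also fine
        s.iloc[5, s.columns.get_loc("TX")] = 25.0
        out, rep = qc_daily(s)
        assert rep.consistency_violations == 1
        assert np.isnan(out["TX"].iloc[5]) and np.isnan(out["TM"].iloc[5])

    def test_flatline_run_flagged(self):
        s = self._series()
        s.iloc[10:16, s.columns.get_loc("RH")] = 77.0
        out, rep = qc_daily(s)
        assert rep.flatline_runs["RH"] == 6
        assert out["RH"].iloc[10:16].isna().all()

    def test_clean_synthetic_series_untouched(self, weather_2y):
        out, rep = qc_daily(weather_2y)
        assert rep.total_flags() == 0
        pd.testing.assert_frame_equal(out, weather_2y)


class TestMerge:
    def _two_series(self):
        i1 = pd.date_range("2020-01-01", periods=10)
        i2 = pd.date_range("2020-01-08", periods=10)
        a = pd.DataFrame({"TX": 30.0, "TM": 22.0, "P": 1.0}, index=i1)
        b = pd.DataFrame({"TX": 31.0, "TM": 23.0, "P": 2.0}, index=i2)
        return a, b

    def test_disjoint_periods_union_without_gaps(self):
        a, b = self._two_series()
        merged, prov, conflicts = merge_station_series(a.iloc[:7], b)
        assert len(merged) == 17
        assert merged.notna().all().all()

    def test_primary_wins_on_overlap(self):
        a, b = self._two_series()
        merged, prov, _ = merge_station_series(a, b)
        assert merged.loc["2020-01-08", "TX"] == 30.0
        assert prov.loc["2020-01-08", "TX"] == "primary"
        assert prov.loc["2020-01-15", "TX"] == "secondary"

    def test_coverage_is_union_of_coverages(self, rng):
        idx = pd.date_range("2020-01-01", periods=60)
        a = pd.DataFrame({"TX": rng.normal(30, 1, 60)}, index=idx)
        b = pd.DataFrame({"TX": rng.normal(30, 1, 60)}, index=idx)
        a[rng.random(60) < 0.4] = np.nan
        b[rng.random(60) < 0.4] = np.nan
        merged, _, _ = merge_station_series(a, b)
        expected = a["TX"].notna() | b["TX"].notna()
        pd.testing.assert_series_equal(merged["TX"].notna(), expected)

    def test_large_overlap_disagreement_logged(self):
        a, b = self._two_series()
        b["TX"] += 5.0
        _, _, conflicts = merge_station_series(a, b)
        assert (conflicts["variable"] == "TX").sum() == 3  # overlap days


class TestDeriveTaDr:
    def test_worked_example(self):
        s = pd.DataFrame({"TX": [30.0], "TM": [20.0]})
        out = derive_ta_dr(s)
        assert out["TA"].iloc[0] == 25.0 and out["DR"].iloc[0] == 10.0

    def test_degenerate_equal_temperatures(self):
        s = pd.DataFrame({"TX": [25.0], "TM": [25.0]})
        out = derive_ta_dr(s)
        assert out["TA"].iloc[0] == 25.0 and out["DR"].iloc[0] == 0.0

    def test_ta_between_tm_and_tx_on_generated_days(self, weather_2y):
        out = derive_ta_dr(weather_2y)
        assert ((out["TM"] <= out["TA"]) & (out["TA"] <= out["TX"])).all()

    def test_half_range_variant(self):
        s = pd.DataFrame({"TX": [30.0], "TM": [20.0]})
        out = derive_ta_dr(s, ta_formula="half_range")
        assert out["TA"].iloc[0] == 5.0


class TestSolar:
    def test_equator_equinox_closed_form(self):
        # declination ~ 0 at the March equinox: Ra -> (24*60/pi)*Gsc*dr
        doy = 80
        dr = 1 + 0.033 * math.cos(2 * math.pi * doy / 365)
        closed = (24 * 60 / math.pi) * 0.0820 * dr
        got = solar.extraterrestrial_radiation_mj(0.0, doy)
        assert abs(got - closed) / closed < 0.01

    def test_published_worked_value_southern_hemisphere(self):
        # 20 deg S on 3 September (doy 246): Ra = 32.2 MJ m-2 day-1
        assert solar.extraterrestrial_radiation_mj(-20.0, 246) == \
            pytest.approx(32.2, abs=0.2)

    def test_hemispheric_symmetry_half_year_apart(self):
        # symmetric once the Earth-Sun distance factor (which is NOT
        # symmetric under a half-year shift) is divided out
        def dr(doy):
            return 1 + 0.033 * math.cos(2 * math.pi * doy / 365)

        for lat in (10.0, 35.0, 55.0):
            a = solar.extraterrestrial_radiation_mj(lat, 32) / dr(32)
            b = solar.extraterrestrial_radiation_mj(-lat, 32 + 183) / dr(215)
            assert abs(a - b) / a < 0.02

    def test_polar_latitudes_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            solar.extraterrestrial_radiation(70.0, 100)

    def test_angstrom_limits_and_midpoint(self):
        lat, doy = 4.0, 150
        ra = solar.extraterrestrial_radiation(lat, doy)
        N = solar.daylength_hours(lat, doy)
        assert solar.solar_from_sunshine(0.0, lat, doy) == pytest.approx(0.25 * ra)
        assert solar.solar_from_sunshine(N, lat, doy) == \
            pytest.approx(0.75 * ra, rel=1e-9)
        assert solar.solar_from_sunshine(N / 2, lat, doy) == \
            pytest.approx(0.50 * ra, rel=1e-9)

    def test_monotone_in_sunshine_hours(self):
        lat, doy = 4.0, 150
        N = solar.daylength_hours(lat, doy)
        vals = [solar.solar_from_sunshine(n, lat, doy)
                for n in np.linspace(0, N, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_excess_sunshine_clipped_with_warning(self):
        lat, doy = 4.0, 150
        N = solar.daylength_hours(lat, doy)
        with pytest.warns(UserWarning, match="clipping"):
            clipped = solar.solar_from_sunshine(N + 2.0, lat, doy)
        assert clipped == pytest.approx(solar.solar_from_sunshine(N, lat, doy))
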