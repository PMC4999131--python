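"""Cropping events: sowing estimation, stage splitting, indicators, cleaning."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riceclim.events import (DEFAULT_PROFILE, INDICATOR_NAMES,
                             CultivarStageProfile, EventError,
                             ImplausibleCycleError, WindowCoverageError,
                             attach_weather_window, build_indicator_table,
                             clean_indicator_table, compute_stage_indicators,
                             estimate_sowing_date, split_growth_stages,
                             standardize_records)


class TestEstimateSowingDate:
    def test_irrigated_site_126_days(self):
        assert estimate_sowing_date("2013-06-30", "Saldana") == \
            dt.date(2013, 2, 24)

    def test_rainfed_site_128_days(self):
        assert estimate_sowing_date("2014-05-08", "Villavicencio") == \
            dt.date(2013, 12, 31)

    def test_unknown_locality_without_default_rejected(self):
        with pytest.raises(EventError, match="no cycle length"):
            estimate_sowing_date("2014-05-08", "Atlantis")
        got = estimate_sowing_date("2014-05-08", "Atlantis", default_cycle=120)
        assert got == dt.date(2014, 5, 8) - dt.timedelta(days=120)


class TestSplitGrowthStages:
    PROFILE = CultivarStageProfile("P", 55, 36, 35)

    def test_identity_scale(self):
        s = split_growth_stages("2020-01-01", "2020-05-06", self.PROFILE)
        assert s.durations == (55, 36, 35)
        assert s.panicle_initiation == dt.date(2020, 2, 25)
        assert s.heading == dt.date(2020, 4, 1)

    def test_largest_remainder_on_140_day_cycle(self):
        s = split_growth_stages("2020-01-01",
                                dt.date(2020, 1, 1) + dt.timedelta(days=140),
                                self.PROFILE)
        # raw (61.11, 40.00, 38.89) -> (61, 40, 39)
        assert s.durations == (61, 40, 39)

    @settings(deadline=None, max_examples=200)
    @given(cycle=st.integers(100, 160),
           profile_idx=st.integers(0, 4))
    def test_stage_lengths_always_sum_to_cycle(self, cycle, profile_idx):
        profiles = [CultivarStageProfile("p", *d) for d in
                    [(55, 36, 35), (60, 33, 33), (50, 40, 36),
                     (58, 35, 33), (45, 45, 36)]]
        s = split_growth_stages(dt.date(2020, 1, 1),
                                dt.date(2020, 1, 1) + dt.timedelta(days=cycle),
                                profiles[profile_idx])
        assert sum(s.durations) == cycle
        assert dt.date(2020, 1, 1) < s.panicle_initiation < s.heading \
            < dt.date(2020, 1, 1) + dt.timedelta(days=cycle)

    @pytest.mark.parametrize("cycle", [59, 201])
    def test_implausible_cycles_rejected(self, cycle):
        with pytest.raises(ImplausibleCycleError):
            split_growth_stages(dt.date(2020, 1, 1),
                                dt.date(2020, 1, 1) + dt.timedelta(days=cycle),
                                self.PROFILE)


def _record(sow="2010-03-01", cycle=126, yld=6000.0):
    sow = pd.Timestamp(sow)
    return {"event_id": "E1", "locality": "synthetic", "cultivar": "default",
            "sowing_date": sow, "harvest_date": sow + pd.Timedelta(days=cycle),
            "yield": yld}


class TestAttachWindow:
    def test_126_day_cycle_gives_127_rows_inclusive(self, weather_2y):
        ev = attach_weather_window(_record(), weather_2y, DEFAULT_PROFILE)
        assert len(ev.window) == 127
        assert ev.window.index[0] == pd.Timestamp("2010-03-01")
        assert ev.window.index[-1] == pd.Timestamp(ev.harvest_date)

    def test_event_outside_coverage_excluded(self, weather_2y):
        with pytest.raises(WindowCoverageError):
            attach_weather_window(_record(sow="2013-01-01"), weather_2y,
                                  DEFAULT_PROFILE)

    def test_missing_day_inside_window_excluded(self, weather_2y):
        holed = weather_2y.copy()
        holed.loc["2010-04-01", "TX"] = np.nan
        with pytest.raises(WindowCoverageError, match="missing"):
            attach_weather_window(_record(), holed, DEFAULT_PROFILE)

    def test_window_values_equal_series_slice(self, weather_2y):
        ev = attach_weather_window(_record(), weather_2y, DEFAULT_PROFILE)
        np.testing.assert_array_equal(
            ev.window["TX"].to_numpy(),
            weather_2y.loc[ev.window.index, "TX"].to_numpy())


def _brute_force_indicators(event):
    """Per-day loop oracle, independent of the vectorized implementation."""
    from riceclim.events import P_HEAVY_MM, TX_THRESHOLDS
    sums = {s: {} for s in ("VEG", "REP", "RIP")}
    for date, row in event.window.iterrows():
        d = date.date()
        if d < event.stages.panicle_initiation:
            stage = "VEG"
        elif d < event.stages.heading:
            stage = "REP"
        else:
            stage = "RIP"
        acc = sums[stage].setdefault(
            "rows", {"n": 0, "tx": [], "tm": [], "p": [], "rh": [], "sr": []})
        acc["n"] += 1
        acc["tx"].append(row["TX"])
        acc["tm"].append(row["TM"])
        acc["p"].append(row["P"])
        acc["rh"].append(row["RH"])
        acc["sr"].append(row["SR"])
    out = {}
    for s in ("VEG", "REP", "RIP"):
        a = sums[s]["rows"]
        tx, tm = np.array(a["tx"]), np.array(a["tm"])
        p, rh, sr = np.array(a["p"]), np.array(a["rh"]), np.array(a["sr"])
        out[f"TX_Avg_{s}"] = tx.mean()
        out[f"TM_Avg_{s}"] = tm.mean()
        out[f"TA_Avg_{s}"] = ((tx + tm) / 2).mean()
        out[f"DR_Avg_{s}"] = (tx - tm).mean()
        thr = TX_THRESHOLDS[s]
        out[f"TX_{int(thr)}_Freq_{s}"] = sum(v > thr for v in tx) / a["n"]
        out[f"P_Accu_{s}"] = p.sum()
        out[f"P_10_Freq_{s}"] = sum(v > P_HEAVY_MM for v in p) / a["n"]
        out[f"RH_Avg_{s}"] = rh.mean()
        out[f"SR_Accu_{s}"] = sr.sum()
    return out


class TestIndicators:
    def test_tx_frequency_worked_example(self, weather_2y):
        ev = attach_weather_window(_record(), weather_2y, DEFAULT_PROFILE)
        ev.window = ev.window.copy()
        ev.window["TX"] = 30.0
        veg_days = ev.stages.veg_days
        ev.window.iloc[:veg_days // 2,
                       ev.window.columns.get_loc("TX")] = 36.0
        row = compute_stage_indicators(ev)
        assert row["TX_35_Freq_VEG"] == pytest.approx((veg_days // 2) / veg_days)

    def test_constant_precip_accumulation_and_frequency(self, weather_2y):
        ev = attach_weather_window(_record(), weather_2y, DEFAULT_PROFILE)
        ev.window = ev.window.copy()
        ev.window["P"] = 5.0
        row = compute_stage_indicators(ev)
        assert row["P_Accu_REP"] == pytest.approx(5.0 * ev.stages.rep_days)
        assert row["P_10_Freq_REP"] == 0.0

    def test_matches_brute_force_loop_exactly(self, weather_2y):
        rng = np.random.default_rng(31)
        for _ in range(20):
            sow = weather_2y.index[rng.integers(0, 500)]
            cycle = int(rng.integers(100, 161))
            ev = attach_weather_window(_record(sow=sow, cycle=cycle),
                                       weather_2y, DEFAULT_PROFILE)
            row = compute_stage_indicators(ev)
            oracle = _brute_force_indicators(ev)
            for name, want in oracle.items():
                assert row[name] == pytest.approx(want, rel=1e-12), name

    def test_row_order_of_window_is_irrelevant(self, weather_2y):
        ev = attach_weather_window(_record(), weather_2y, DEFAULT_PROFILE)
        a = compute_stage_indicators(ev)
        ev.window = ev.window.sample(frac=1.0, random_state=5)
        b = compute_stage_indicators(ev)
        pd.testing.assert_series_equal(a, b)

    def test_indicator_row_invariants(self, weather_2y):
        events = pd.DataFrame([_record()])
        table, log = build_indicator_table(events, weather_2y)
        assert log.empty
        row = table.iloc[0]
        for s in ("VEG", "REP", "RIP"):
            assert row[f"TM_Avg_{s}"] <= row[f"TA_Avg_{s}"] <= row[f"TX_Avg_{s}"]
            assert row[f"DR_Avg_{s}"] >= 0
            assert row[f"P_Accu_{s}"] >= 0 and row[f"SR_Accu_{s}"] >= 0
        freq_cols = [c for c in INDICATOR_NAMES if "Freq" in c]
        assert ((table[freq_cols] >= 0) & (table[freq_cols] <= 1)).all().all()


class TestCleanTable:
    def _table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        data = {c: rng.normal(10, 1, n) for c in INDICATOR_NAMES}
        data["event_id"] = [f"E{i}" for i in range(n)]
        data["Cultivar"] = "A"
        data["Yield"] = rng.normal(6000, 300, n)
        return pd.DataFrame(data)

    def test_constant_predictor_dropped(self):
        t = self._table()
        t["TX_Avg_VEG"] = 33.0
        cleaned, log = clean_indicator_table(t)
        assert "TX_Avg_VEG" not in cleaned.columns
        assert ((log["kind"] == "column") & (log["name"] == "TX_Avg_VEG")).any()

    def test_extreme_yield_row_dropped(self):
        t = self._table()
        t.loc[7, "Yield"] = 60000.0
        cleaned, log = clean_indicator_table(t)
        assert "E7" not in set(cleaned["event_id"])
        assert ((log["kind"] == "row") & (log["name"] == "E7")).any()

    def test_well_behaved_table_essentially_untouched(self):
        # the median +/- 3*IQR fence sits at ~4 sd for Gaussian columns, so a
        # well-behaved table loses no columns and at most a stray row
        t = self._table()
        cleaned, log = clean_indicator_table(t)
        assert not (log["kind"] == "column").any()
        assert len(cleaned) >= 0.98 * len(t)

    def test_all_rows_removed_is_an_error(self):
        t = self._table()
        with pytest.raises(ValueError, match="every event"):
            clean_indicator_table(t, iqr_mult=0.0)


class TestStandardizeRecords:
    RAW = pd.DataFrame({
        "muni": ["Saldana"] * 5,
        "variety": ["f-733", "F733", "F2000", "F2000", "F2000"],
        "harvest": ["2013-06-30", "2013-07-30", "2013-08-30", "2013-08-30",
                    "2013-09-30"],
        "sow": [None, None, "2013-05-01", None, "2013-10-30"],
        "prod": [6000.0, 5500.0, 5000.0, 5000.0, 4800.0],
    })
    CMAP = {"muni": "locality", "variety": "cultivar", "harvest": "harvest_date",
            "sow": "sowing_date", "prod": "yield"}

    def test_alias_canonicalization(self):
        out, _ = standardize_records(self.RAW, self.CMAP, {"f733": "F733"})
        assert set(out["cultivar"]) == {"F733", "F2000"}

    def test_duplicates_collapsed_and_incoherent_removed(self):
        out, log = standardize_records(self.RAW, self.CMAP, {"f733": "F733"})
        # row 3 duplicates row 2 on the key; row 4 sows after harvesting
        assert len(out) == 3
        assert set(log["reason"]) == {"duplicate record",
                                      "sowing on/after harvest"}

    def test_unmappable_mandatory_column_rejected(self):
        with pytest.raises(ValueError, match="mandatory"):
            standardize_records(self.RAW.drop(columns="prod"),
                                {k: v for k, v in self.CMAP.items()
                                 if k != "prod"})
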