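"""Station screening, hourly aggregation, daily QC and series merging.

Turns raw station records into one complete, quality-controlled daily series
per locality: screen stations by distance and altitude, aggregate hourly
records to daily values (a day is kept only when strictly more than 80% of
its hours are valid), flag and blank physically impossible or internally
inconsistent values, merge stations with complementary recording periods,
and derive mean temperature TA = (TX+TM)/2 and diurnal range DR = TX-TM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIABLES = ("TX", "TM", "P", "RH", "SR")

EARTH_RADIUS_KM = 6371.0088


class NoEligibleStationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StationMeta:
    station_id: str
    latitude_deg: float
    longitude_deg: float
    altitude_m: float
    provider: str = ""

    def __post_init__(self):
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError("latitude outside [-90, 90]")
        if not math.isfinite(self.altitude_m):
            raise ValueError("altitude must be finite")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def select_stations(stations: list[StationMeta], crop_lat: float, crop_lon: float,
                    crop_alt_m: float, max_dist_km: float = 10.0,
                    alt_tol_m: float = 50.0) -> list[tuple[StationMeta, float]]:
    """Stations within ``max_dist_km`` (strict) and ``+/- alt_tol_m`` of the crop.

    Returns (station, distance_km) pairs sorted by distance; raises
    :class:`NoEligibleStationError` when none qualifies.
    """
    out = []
    for s in stations:
        d = haversine_km(s.latitude_deg, s.longitude_deg, crop_lat, crop_lon)
        if d < max_dist_km and abs(s.altitude_m - crop_alt_m) <= alt_tol_m:
            out.append((s, d))
    if not out:
        raise NoEligibleStationError(
            f"no station within {max_dist_km} km and +/-{alt_tol_m} m altitude")
    return sorted(out, key=lambda t: t[1])


def aggregate_hourly_to_daily(hourly: pd.DataFrame,
                              min_completeness: float = 0.8,
                              timestamp_col: str = "timestamp",
                              temp_col: str = "temp", precip_col: str = "precip",
                              rh_col: str = "rh", sr_col: str = "sr",
                              ) -> pd.DataFrame:
    """Aggregate hourly records to daily TX/TM/P/RH/SR.

    Per variable, a day's value is computed only when strictly more than
    ``min_completeness * 24`` hours are valid (e.g. at the default 0.8 rule,
    19 valid hours is rejected, 20 is kept): TX = max and TM = min of hourly
    temperature, P = sum, RH = mean, SR = sum.  Duplicate timestamps are
    rejected naming the offending day.
    """
    ts = pd.to_datetime(hourly[timestamp_col])
    if ts.duplicated().any():
        day = ts[ts.duplicated()].dt.date.iloc[0]
        raise ValueError(f"duplicate hourly timestamps on {day}")
    df = hourly.copy()
    df["_day"] = ts.dt.normalize()
    need = min_completeness * 24.0

    def agg(col, how):
        g = df.groupby("_day")[col]
        val = g.agg(how)
        val[g.count() <= need] = np.nan  # strict: count must exceed the rule
        return val

    out = pd.DataFrame({
        "TX": agg(temp_col, "max"),
        "TM": agg(temp_col, "min"),
        "P": agg(precip_col, "sum"),
        "RH": agg(rh_col, "mean"),
        "SR": agg(sr_col, "sum"),
    })
    out.index = pd.DatetimeIndex(out.index, name="date")
    return out


@dataclass(frozen=True)
class QCLimits:
    """Plausibility limits for a tropical lowland site; fully configurable
    (guideline-style QC: the numeric bounds themselves are site decisions)."""

    tx_range: tuple[float, float] = (10.0, 45.0)
    tm_range: tuple[float, float] = (5.0, 35.0)
    p_range: tuple[float, float] = (0.0, 300.0)
    rh_range: tuple[float, float] = (0.0, 100.0)
    sr_range: tuple[float, float] = (0.0, 900.0)  # lower bound exclusive
    flatline_days: int = 5


@dataclass
class QCReport:
    range_violations: dict = field(default_factory=dict)
    consistency_violations: int = 0
    flatline_runs: dict = field(default_factory=dict)
    set_missing: dict = field(default_factory=dict)

    def total_flags(self) -> int:
        return (sum(self.range_violations.values())
                + 2 * self.consistency_violations
                + sum(self.flatline_runs.values()))


def _flatline_mask(x: pd.Series, min_run: int) -> np.ndarray:
    v = x.to_numpy()
    runs = np.zeros(len(v), dtype=bool)
    i = 0
    while i < len(v):
        j = i
        while (j + 1 < len(v) and np.isfinite(v[j + 1]) and np.isfinite(v[i])
               and v[j + 1] == v[i]):
            j += 1
        if np.isfinite(v[i]) and j - i + 1 >= min_run:
            runs[i:j + 1] = True
        i = j + 1
    return runs


def qc_daily(series: pd.DataFrame, limits: QCLimits | None = None,
             ) -> tuple[pd.DataFrame, QCReport]:
    """Flag and blank out-of-range values, TM>TX days, and flatline runs.

    QC never aborts: offending cells are set to missing and counted in the
    report (TM>TX flags both temperatures; flatlines apply to TX, TM and RH).
    """
    limits = limits or QCLimits()
    out = series.copy()
    rep = QCReport()
    ranges = {"TX": limits.tx_range, "TM": limits.tm_range, "P": limits.p_range,
              "RH": limits.rh_range, "SR": limits.sr_range}
    for var, (lo, hi) in ranges.items():
        if var not in out.columns:
            continue
        col = out[var]
        bad = (col < lo) | (col > hi)
        if var == "SR":
            bad = (col <= lo) | (col > hi)  # SR must be strictly positive
        rep.range_violations[var] = int(bad.sum())
        out.loc[bad, var] = np.nan
    if {"TX", "TM"} <= set(out.columns):
        inc = out["TM"] > out["TX"]
        rep.consistency_violations = int(inc.sum())
        out.loc[inc, ["TX", "TM"]] = np.nan
    for var in ("TX", "TM", "RH"):
        if var not in out.columns:
            continue
        flat = _flatline_mask(out[var], limits.flatline_days)
        rep.flatline_runs[var] = int(flat.sum())
        out.loc[flat, var] = np.nan
    for var in out.columns:
        if var in series.columns:
            rep.set_missing[var] = int(out[var].isna().sum() - series[var].isna().sum())
    return out, rep


def merge_station_series(primary: pd.DataFrame, secondary: pd.DataFrame,
                         temp_tol: float = 2.0, p_rel_tol: float = 0.2,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Merge two stations with complementary recording periods.

    Per day and variable the primary value wins when present, otherwise the
    secondary fills in.  Days where both are present and disagree beyond
    tolerance (2 deg C for temperatures, 20% relative for precipitation) are
    logged but the primary is kept.  Returns (merged, provenance, conflicts).
    """
    if set(primary.columns) != set(secondary.columns):
        raise ValueError("primary and secondary must share the same variable set")
    idx = primary.index.union(secondary.index)
    a = primary.reindex(idx)
    b = secondary.reindex(idx)
    merged = a.combine_first(b)
    prov = pd.DataFrame("", index=idx, columns=primary.columns)
    prov = prov.mask(a.notna(), "primary").mask(a.isna() & b.notna(), "secondary")
    conflicts = []
    for var in primary.columns:
        both = a[var].notna() & b[var].notna()
        diff = (a[var] - b[var]).abs()
        if var in ("TX", "TM", "TA"):
            bad = both & (diff > temp_tol)
        elif var == "P":
            denom = pd.concat([a[var].abs(), b[var].abs()], axis=1).max(axis=1)
            bad = both & (denom > 0) & (diff / denom.replace(0, np.nan) > p_rel_tol)
        else:
            bad = both & False
        for d in idx[bad.fillna(False)]:
            conflicts.append({"date": d, "variable": var,
                              "primary": a.loc[d, var], "secondary": b.loc[d, var]})
    return merged, prov, pd.DataFrame(conflicts,
                                      columns=["date", "variable",
                                               "primary", "secondary"])


def derive_ta_dr(series: pd.DataFrame, ta_formula: str = "mean") -> pd.DataFrame:
    """Add mean temperature TA and diurnal range DR = TX - TM.

    ``ta_formula="mean"`` computes TA = (TX+TM)/2 so that TM <= TA <= TX;
    ``ta_formula="half_range"`` computes (TX-TM)/2 instead, a half-range
    variant sometimes seen in print.
    """
    out = series.copy()
    if ta_formula == "mean":
        out["TA"] = (out["TX"] + out["TM"]) / 2.0
    elif ta_formula == "half_range":
        out["TA"] = (out["TX"] - out["TM"]) / 2.0
    else:
        raise ValueError(f"unknown ta_formula {ta_formula!r}")
    out["DR"] = out["TX"] - out["TM"]
    return out
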