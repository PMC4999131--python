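"""Cropping events, growth stages and stage-wise agro-climatic indicators.

The analysis unit is the *cropping event*: one harvest record (locality,
cultivar, sowing date, harvest date, yield) joined to the daily weather the
crop experienced between sowing and harvest.  The cycle is split into the
three rice growth stages — vegetative (VEG, germination to panicle-primordia
initiation), reproductive (REP, to heading) and ripening (RIP, to maturity) —
by scaling cultivar-specific reference durations to the actual cycle length.
Per stage, 9 climatic indicators are computed (27 predictors in total).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("VEG", "REP", "RIP")

#: High-temperature exceedance thresholds (deg C) per stage: sterility-relevant
#: maxima differ between stages (35 vegetative, 37 reproductive, 31 ripening).
TX_THRESHOLDS = {"VEG": 35.0, "REP": 37.0, "RIP": 31.0}

#: Heavy-rain day threshold (mm).
P_HEAVY_MM = 10.0

#: The 27 continuous stage indicators, in canonical order.
INDICATOR_NAMES = (
    [f"TX_Avg_{s}" for s in STAGES]
    + [f"TM_Avg_{s}" for s in STAGES]
    + [f"TA_Avg_{s}" for s in STAGES]
    + [f"DR_Avg_{s}" for s in STAGES]
    + ["TX_35_Freq_VEG", "TX_37_Freq_REP", "TX_31_Freq_RIP"]
    + [f"P_Accu_{s}" for s in STAGES]
    + [f"P_10_Freq_{s}" for s in STAGES]
    + [f"RH_Avg_{s}" for s in STAGES]
    + [f"SR_Accu_{s}" for s in STAGES]
)

#: Default assumed cycle length (days) per locality when the sowing date is
#: missing: 126 for the irrigated site, 128 for the rainfed site.
DEFAULT_CYCLE_DAYS = {"Saldana": 126, "Saldaña": 126,
                      "Villavicencio": 128}


class EventError(ValueError):
    """A cropping event could not be built; carries a machine-readable reason."""


class ImplausibleCycleError(EventError):
    pass


class WindowCoverageError(EventError):
    pass


@dataclass(frozen=True)
class CultivarStageProfile:
    """Reference stage durations for one cultivar on a fixed reference cycle."""

    cultivar: str
    veg_days: int
    rep_days: int
    rip_days: int
    reference_cycle: int = 126

    def __post_init__(self):
        if min(self.veg_days, self.rep_days, self.rip_days) <= 0:
            raise ValueError("stage durations must be positive")
        total = self.veg_days + self.rep_days + self.rip_days
        if total != self.reference_cycle:
            raise ValueError(
                f"stage durations sum to {total}, expected reference cycle "
                f"{self.reference_cycle}"
            )

    @property
    def durations(self) -> tuple[int, int, int]:
        return (self.veg_days, self.rep_days, self.rip_days)


#: A generic medium-cycle profile; real profiles are configuration supplied by
#: agronomists, these ship only as plausible defaults.
DEFAULT_PROFILE = CultivarStageProfile("default", 55, 36, 35)


@dataclass
class StageSplit:
    veg_days: int
    rep_days: int
    rip_days: int
    panicle_initiation: dt.date
    heading: dt.date

    @property
    def durations(self) -> tuple[int, int, int]:
        return (self.veg_days, self.rep_days, self.rip_days)


@dataclass
class CroppingEvent:
    event_id: str
    locality: str
    cultivar: str
    sowing_date: dt.date
    harvest_date: dt.date
    yield_kg_ha: float
    stages: StageSplit
    window: pd.DataFrame  # daily weather, inclusive of sowing and harvest


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def estimate_sowing_date(harvest_date, locality: str,
                         cycle_map: dict[str, int] | None = None,
                         default_cycle: int | None = None) -> dt.date:
    """Back-date sowing from harvest using the locality's typical cycle length.

    Applied only when the sowing date is absent from the record; the default
    map uses 126 days (irrigated site) and 128 days (rainfed site).
    """
    cycle_map = DEFAULT_CYCLE_DAYS if cycle_map is None else cycle_map
    if locality not in cycle_map:
        if default_cycle is None:
            raise EventError(f"no cycle length configured for locality {locality!r}")
        days = default_cycle
    else:
        days = cycle_map[locality]
    return _as_date(harvest_date) - dt.timedelta(days=int(days))


def split_growth_stages(sowing, harvest,
                        profile: CultivarStageProfile) -> StageSplit:
    """Scale the cultivar's reference stage durations to the actual cycle.

    Stage lengths are ``round(profile * actual/reference)`` with
    largest-remainder rounding so they always sum exactly to the actual cycle
    length (``harvest - sowing`` in days).  Boundaries are cumulative from
    sowing: panicle initiation at sowing+VEG, heading at sowing+VEG+REP.
    """
    sowing, harvest = _as_date(sowing), _as_date(harvest)
    actual = (harvest - sowing).days
    if actual <= 0:
        raise EventError("harvest date must be after sowing date")
    if actual < 60 or actual > 200:
        raise ImplausibleCycleError(
            f"cycle of {actual} days outside plausible range [60, 200]"
        )
    scale = actual / profile.reference_cycle
    raw = np.asarray(profile.durations, dtype=float) * scale
    lengths = np.floor(raw).astype(int)
    short = actual - int(lengths.sum())
    # distribute the remainder to the largest fractional parts (ties: first stage)
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    for i in range(short):
        lengths[order[i]] += 1
    if lengths.min() <= 0:
        raise ImplausibleCycleError("a growth stage collapsed to zero days")
    pi = sowing + dt.timedelta(days=int(lengths[0]))
    heading = pi + dt.timedelta(days=int(lengths[1]))
    return StageSplit(int(lengths[0]), int(lengths[1]), int(lengths[2]), pi, heading)


def attach_weather_window(record, series: pd.DataFrame,
                          profile: CultivarStageProfile) -> CroppingEvent:
    """Join one harvest record to its sowing-to-harvest daily weather window.

    ``record`` must expose event_id, locality, cultivar, sowing_date,
    harvest_date and yield (mapping or pandas row).  The window includes both
    the sowing and the harvest day; a coverage gap or missing cell inside the
    window raises :class:`WindowCoverageError` so the caller can log and
    exclude the event.
    """
    get = record.get if hasattr(record, "get") else record.__getitem__
    sowing = _as_date(get("sowing_date"))
    harvest = _as_date(get("harvest_date"))
    stages = split_growth_stages(sowing, harvest, profile)
    idx = pd.date_range(sowing, harvest, freq="D")
    if not idx.isin(series.index).all():
        raise WindowCoverageError(
            f"weather series does not cover [{sowing}, {harvest}]"
        )
    window = series.loc[idx].copy()
    core = [c for c in ("TX", "TM", "P", "RH", "SR") if c in window.columns]
    if window[core].isna().any().any():
        raise WindowCoverageError("missing weather values inside the event window")
    return CroppingEvent(
        event_id=str(get("event_id")),
        locality=str(get("locality")),
        cultivar=str(get("cultivar")),
        sowing_date=sowing,
        harvest_date=harvest,
        yield_kg_ha=float(get("yield")) if not pd.isna(get("yield")) else np.nan,
        stages=stages,
        window=window,
    )


def _stage_masks(dates: pd.DatetimeIndex, stages: StageSplit,
                 ) -> dict[str, np.ndarray]:
    """Half-open stage membership [start, next_start); RIP keeps the harvest day."""
    pi = pd.Timestamp(stages.panicle_initiation)
    hd = pd.Timestamp(stages.heading)
    veg = dates < pi
    rep = (dates >= pi) & (dates < hd)
    rip = dates >= hd
    return {"VEG": np.asarray(veg), "REP": np.asarray(rep), "RIP": np.asarray(rip)}


def compute_stage_indicators(event: CroppingEvent) -> pd.Series:
    """Compute the 27 stage indicators for one event.

    Averages are arithmetic means over stage days; accumulations are sums;
    frequencies are proportions of stage days with strict threshold
    exceedance (TX above 35/37/31 deg C per stage, P above 10 mm).
    """
    w = event.window.sort_index()
    if "TA" not in w.columns or "DR" not in w.columns:
        w = w.assign(TA=(w["TX"] + w["TM"]) / 2.0, DR=w["TX"] - w["TM"])
    masks = _stage_masks(w.index, event.stages)
    out: dict[str, float] = {"event_id": event.event_id, "Cultivar": event.cultivar}
    for s in STAGES:
        m = masks[s]
        ndays = int(m.sum())
        if ndays == 0:
            raise EventError(f"empty {s} stage in event {event.event_id}")
        tx = w["TX"].to_numpy()[m]
        out[f"TX_Avg_{s}"] = float(tx.mean())
        out[f"TM_Avg_{s}"] = float(w["TM"].to_numpy()[m].mean())
        out[f"TA_Avg_{s}"] = float(w["TA"].to_numpy()[m].mean())
        out[f"DR_Avg_{s}"] = float(w["DR"].to_numpy()[m].mean())
        thr = TX_THRESHOLDS[s]
        out[f"TX_{int(thr)}_Freq_{s}"] = float((tx > thr).sum() / ndays)
        p = w["P"].to_numpy()[m]
        out[f"P_Accu_{s}"] = float(p.sum())
        out[f"P_10_Freq_{s}"] = float((p > P_HEAVY_MM).sum() / ndays)
        out[f"RH_Avg_{s}"] = float(w["RH"].to_numpy()[m].mean())
        out[f"SR_Accu_{s}"] = float(w["SR"].to_numpy()[m].sum())
    out["Yield"] = event.yield_kg_ha
    cols = ["event_id", "Cultivar"] + INDICATOR_NAMES + ["Yield"]
    return pd.Series(out)[cols]


def build_indicator_table(events_df: pd.DataFrame, series: pd.DataFrame,
                          profiles: dict[str, CultivarStageProfile] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the events x indicators table; returns (table, exclusion log)."""
    profiles = profiles or {}
    rows, excluded = [], []
    for _, rec in events_df.iterrows():
        profile = profiles.get(rec["cultivar"], DEFAULT_PROFILE)
        try:
            ev = attach_weather_window(rec, series, profile)
            rows.append(compute_stage_indicators(ev))
        except EventError as err:
            excluded.append({"event_id": rec["event_id"], "reason": str(err)})
    if not rows:
        raise EventError("no events survived window attachment")
    table = pd.DataFrame(rows).reset_index(drop=True)
    log = pd.DataFrame(excluded, columns=["event_id", "reason"])
    return table, log


def clean_indicator_table(table: pd.DataFrame, variance_tol: float = 1e-8,
                          cv_tol: float | None = None, iqr_mult: float = 3.0,
                          by: str | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop near-constant predictors and fence outlying events.

    Predictor columns with standard deviation below ``variance_tol`` (or, when
    ``cv_tol`` is set, coefficient of variation below it) are removed; event
    rows where yield or any surviving predictor falls outside
    median +/- ``iqr_mult`` x IQR (per ``by`` group when given) are removed.
    Every removal is logged with its reason.
    """
    if table.empty:
        raise ValueError("empty indicator table")
    log: list[dict] = []
    preds = [c for c in INDICATOR_NAMES if c in table.columns]
    keep_cols = []
    for c in preds:
        col = table[c].astype(float)
        sd = col.std(ddof=0)
        if sd < variance_tol:
            log.append({"kind": "column", "name": c, "reason": "near-zero variance"})
            continue
        if cv_tol is not None:
            mu = abs(col.mean())
            if mu > 0 and sd / mu < cv_tol:
                log.append({"kind": "column", "name": c,
                            "reason": f"coefficient of variation < {cv_tol}"})
                continue
        keep_cols.append(c)

    fenced = ["Yield"] + keep_cols
    groups = table.groupby(by) if by and by in table.columns else [(None, table)]
    bad_rows: set = set()
    for _, g in groups:
        for c in fenced:
            col = g[c].astype(float)
            q1, med, q3 = col.quantile([0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo, hi = med - iqr_mult * iqr, med + iqr_mult * iqr
            out = g.index[(col < lo) | (col > hi)]
            for i in out:
                if i not in bad_rows:
                    log.append({"kind": "row",
                                "name": str(table.loc[i].get("event_id", i)),
                                "reason": f"{c} outside median +/- {iqr_mult}*IQR"})
                bad_rows.add(i)
    cleaned = table.drop(index=sorted(bad_rows))
    other = [c for c in table.columns if c not in preds]
    cleaned = cleaned[[c for c in table.columns if c in other or c in keep_cols]]
    if cleaned.empty:
        raise ValueError("cleaning removed every event row")
    return cleaned.reset_index(drop=True), pd.DataFrame(
        log, columns=["kind", "name", "reason"])


def standardize_records(raw: pd.DataFrame,
                        column_map: dict[str, str] | None = None,
                        alias_map: dict[str, str] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonicalize raw harvest records.

    ``column_map`` renames input columns to the canonical set (event_id,
    locality, cultivar, sowing_date, harvest_date, yield); ``alias_map`` maps
    normalized spellings (case/punctuation-insensitive) to canonical cultivar
    or locality names.  Exact duplicates on (locality, cultivar, harvest_date,
    yield) are collapsed and incoherent rows (yield <= 0, harvest before
    sowing) removed; a log records every removal.
    """
    df = raw.rename(columns=column_map or {}).copy()
    mandatory = ["locality", "cultivar", "harvest_date", "yield"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"unmappable mandatory column(s): {missing}")
    if "event_id" not in df.columns:
        df["event_id"] = [f"E{i:05d}" for i in range(len(df))]
    if "sowing_date" not in df.columns:
        df["sowing_date"] = pd.NaT

    def canon(x: str) -> str:
        key = "".join(ch for ch in str(x).casefold() if ch.isalnum())
        return (alias_map or {}).get(key, str(x).strip())

    df["cultivar"] = df["cultivar"].map(canon)
    df["locality"] = df["locality"].map(canon)
    df["harvest_date"] = pd.to_datetime(df["harvest_date"])
    df["sowing_date"] = pd.to_datetime(df["sowing_date"], errors="coerce")

    log: list[dict] = []
    dup = df.duplicated(subset=["locality", "cultivar", "harvest_date", "yield"])
    for eid in df.loc[dup, "event_id"]:
        log.append({"event_id": eid, "reason": "duplicate record"})
    df = df[~dup]
    bad_yield = ~(df["yield"].astype(float) > 0)
    for eid in df.loc[bad_yield, "event_id"]:
        log.append({"event_id": eid, "reason": "non-positive yield"})
    df = df[~bad_yield]
    incoherent = df["sowing_date"].notna() & (df["sowing_date"] >= df["harvest_date"])
    for eid in df.loc[incoherent, "event_id"]:
        log.append({"event_id": eid, "reason": "sowing on/after harvest"})
    df = df[~incoherent]
    cols = ["event_id", "locality", "cultivar", "sowing_date", "harvest_date", "yield"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra].reset_index(drop=True), pd.DataFrame(
        log, columns=["event_id", "reason"])
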