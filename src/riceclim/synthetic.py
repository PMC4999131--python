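"""Synthetic tropical weather, cropping events and yields with known truth.

The weather model is a minimal structural emulator of a lowland tropical
station: maximum temperature is a seasonal harmonic plus an AR(1) anomaly;
the diurnal range is drawn independently (smaller on wet days) and minimum
temperature is TX - DR, so TM < TX holds by construction; precipitation
follows a two-state wet/dry Markov chain with gamma amounts and a seasonally
modulated wet probability (optionally bimodal, as in the irrigated study
region); relative humidity is inversely coupled to the diurnal range; solar
radiation is a clear-sky value scaled down on cloudy (wet) days.  Yields are
generated from a known response over the 27 stage indicators (linear, hinge
and saturating driver terms plus cultivar effects and Gaussian noise), so
every downstream stage can be validated against ground truth.

Randomness is split deterministically across variables from one integer
seed (``numpy.random.SeedSequence``): adding a variable never perturbs the
draws of earlier ones.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .dtw import EventSeriesBundle
from .events import INDICATOR_NAMES, CultivarStageProfile

#: Yields are truncated from below at this floor (kg/ha) so extreme noise
#: draws never produce non-physical negative yields.
YIELD_FLOOR = 500.0


@dataclass(frozen=True)
class WeatherGenParams:
    """Parameters of the daily weather emulator (tropical lowland defaults)."""

    latitude_deg: float = 3.9
    tx_mean: float = 32.0           # deg C
    tx_seasonal_amp: float = 0.8    # deg C (tropical lowlands: nearly flat)
    tx_seasonal_phase: float = 80.0  # day of year of the warm peak
    ar1_coef: float = 0.7           # lag-1 autocorrelation of TX anomalies
    tx_noise_sd: float = 1.8        # stationary sd of TX anomalies, deg C
    dr_mean: float = 9.5            # diurnal range, deg C
    dr_tx_coef: float = 0.7         # DR gain per deg C of TX anomaly (clear
    #                                 hot days have larger diurnal ranges, so
    #                                 TM varies less than TX)
    dr_sd: float = 0.7              # sd of DR's own AR(1) anomaly
    dr_ar1: float = 0.6             # persistence of cloudy/clear spells
    dr_wet_drop: float = 1.0        # DR reduction on wet days, deg C
    precip_wet_prob: float = 0.45   # stationary wet-day probability
    precip_persistence: float = 0.6  # wet-state persistence of the Markov chain
    precip_seasonal_amp: float = 0.45  # relative seasonal modulation of wet prob
    bimodal_precip: bool = True     # two rainy seasons per year
    precip_gamma_shape: float = 0.9
    precip_gamma_scale: float = 13.0  # mm
    rh_base: float = 82.0           # %
    rh_dr_coef: float = 2.2         # % per deg C of diurnal-range anomaly
    rh_wet_gain: float = 4.0        # % added on wet days
    rh_noise_sd: float = 3.0
    sr_clear_sky: float = 600.0     # cal cm-2 day-1
    sr_dry_frac: float = 0.75       # transmitted fraction on dry days
    sr_wet_drop: float = 0.20       # extra attenuation on wet days
    sr_noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("bimodal_precip",):
                continue
            if not math.isfinite(float(v)):
                raise ValueError(f"parameter {f.name} must be finite")
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in (-1, 1)")
        if not -1.0 < self.dr_ar1 < 1.0:
            raise ValueError("dr_ar1 must lie in (-1, 1)")
        if not 0.0 <= self.precip_wet_prob < 1.0:
            raise ValueError("precip_wet_prob must lie in [0, 1)")
        if not 0.0 <= self.precip_persistence < 1.0:
            raise ValueError("precip_persistence must lie in [0, 1)")
        for name in ("tx_noise_sd", "dr_sd", "rh_noise_sd", "sr_noise_sd",
                     "precip_gamma_shape", "precip_gamma_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_daily_weather(params: WeatherGenParams, start_date,
                           n_days: int) -> pd.DataFrame:
    """Generate a date-indexed daily series with columns TX, TM, P, RH, SR.

    Deterministic given ``params.seed``.  On every day TM < TX, P >= 0,
    0 <= RH <= 100 and SR > 0.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    dates = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    tx_rng, dr_rng, occ_rng, amt_rng, rh_rng, sr_rng = _spawn_rngs(params.seed, 6)

    harmonic = params.tx_mean + params.tx_seasonal_amp * np.cos(
        2 * np.pi * (doy - params.tx_seasonal_phase) / 365.25)
    phi = params.ar1_coef
    innov_sd = params.tx_noise_sd * math.sqrt(max(1.0 - phi * phi, 0.0))
    eps = tx_rng.normal(0.0, 1.0, n_days)
    if params.tx_noise_sd == 0:
        anom = np.zeros(n_days)
    else:
        anom = lfilter([1.0], [1.0, -phi], innov_sd * eps,
                       zi=[phi * tx_rng.normal(0.0, params.tx_noise_sd)])[0]
    tx = harmonic + anom

    # seasonally modulated wet-day probability (frequency doubled if bimodal)
    cycles = 2.0 if params.bimodal_precip else 1.0
    pi_t = params.precip_wet_prob * (
        1.0 + params.precip_seasonal_amp * np.cos(
            cycles * 2 * np.pi * (doy - 105.0) / 365.25))
    pi_t = np.clip(pi_t, 0.0, 0.98)
    rho = params.precip_persistence
    u = occ_rng.random(n_days)
    wet = np.zeros(n_days, dtype=bool)
    state = u[0] < pi_t[0]
    wet[0] = state
    for i in range(1, n_days):
        p_wet = pi_t[i] + rho * (1.0 - pi_t[i]) if state else pi_t[i] * (1.0 - rho)
        state = u[i] < p_wet
        wet[i] = state
    if params.precip_gamma_shape > 0:
        amounts = amt_rng.gamma(params.precip_gamma_shape,
                                params.precip_gamma_scale, n_days)
    else:
        amounts = np.zeros(n_days)
    p = np.where(wet, amounts, 0.0)

    dr = (params.dr_mean + params.dr_tx_coef * anom
          - params.dr_wet_drop * wet)
    if params.dr_sd > 0:
        psi = params.dr_ar1
        dr_innov = params.dr_sd * math.sqrt(max(1.0 - psi * psi, 0.0))
        dr_eps = dr_rng.normal(0.0, 1.0, n_days)
        dr_anom = lfilter([1.0], [1.0, -psi], dr_innov * dr_eps,
                          zi=[psi * dr_rng.normal(0.0, params.dr_sd)])[0]
        dr = dr + dr_anom
    dr = np.clip(dr, 0.3, None)
    tm = tx - dr

    rh = (params.rh_base - params.rh_dr_coef * (dr - params.dr_mean)
          + params.rh_wet_gain * wet)
    if params.rh_noise_sd > 0:
        rh = rh + rh_rng.normal(0.0, params.rh_noise_sd, n_days)
    rh = np.clip(rh, 0.0, 100.0)

    sr = params.sr_clear_sky * (params.sr_dry_frac - params.sr_wet_drop * wet)
    if params.sr_noise_sd > 0:
        sr = sr + sr_rng.normal(0.0, params.sr_noise_sd, n_days)
    sr = np.clip(sr, 1.0, None)

    return pd.DataFrame({"TX": tx, "TM": tm, "P": p, "RH": rh, "SR": sr},
                        index=dates.rename("date"))


def generate_cropping_events(weather: pd.DataFrame, n_events: int,
                             cultivars: list[CultivarStageProfile],
                             sowing_window: tuple, cycle_days_mean: float = 126.0,
                             cycle_days_sd: float = 6.0, seed: int = 0,
                             cultivar_probs: list[float] | None = None,
                             locality: str = "synthetic") -> pd.DataFrame:
    """Draw cropping events (yield unset) inside the weather coverage.

    Sowing dates are uniform over ``sowing_window``; cycle lengths are
    ``round(Normal(mean, sd))`` clipped to [100, 160] days; cultivars are
    drawn from the supplied profiles (optionally with probabilities).
    """
    start = pd.Timestamp(sowing_window[0])
    end = pd.Timestamp(sowing_window[1])
    if start > end:
        raise ValueError("empty sowing window")
    if (start < weather.index[0]
            or end + pd.Timedelta(days=160) > weather.index[-1]):
        raise ValueError("sowing window plus maximum cycle exceeds weather coverage")
    rng = np.random.default_rng(seed)
    n_window = (end - start).days + 1
    offsets = rng.integers(0, n_window, n_events)
    if cycle_days_sd > 0:
        cycles = np.clip(np.round(rng.normal(cycle_days_mean, cycle_days_sd,
                                             n_events)), 100, 160).astype(int)
    else:
        cycles = np.full(n_events, int(round(cycle_days_mean)))
    names = [c.cultivar for c in cultivars]
    cult = rng.choice(names, size=n_events, p=cultivar_probs)
    sowing = start + pd.to_timedelta(offsets, unit="D")
    harvest = sowing + pd.to_timedelta(cycles, unit="D")
    return pd.DataFrame({
        "event_id": [f"E{i:05d}" for i in range(n_events)],
        "locality": locality,
        "cultivar": cult,
        "sowing_date": sowing,
        "harvest_date": harvest,
        "yield": np.nan,
    })


@dataclass(frozen=True)
class DriverTerm:
    """One known driver of yield: linear, hinge(breakpoint) or saturating."""

    indicator: str
    form: str                      # "linear" | "hinge" | "saturating"
    coefficient: float
    breakpoint: float | None = None  # hinge: contributes coef*max(0, x - b)
    scale: float | None = None       # saturating: coef*(1 - exp(-x/scale))

    def __post_init__(self):
        if self.indicator not in INDICATOR_NAMES:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.form not in ("linear", "hinge", "saturating"):
            raise ValueError(f"unknown functional form {self.form!r}")
        if self.form == "hinge" and self.breakpoint is None:
            raise ValueError("hinge term needs a breakpoint")
        if self.form == "saturating" and (self.scale is None or self.scale <= 0):
            raise ValueError("saturating term needs a positive scale")

    def contribution(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.coefficient * x
        if self.form == "hinge":
            return self.coefficient * np.maximum(0.0, x - self.breakpoint)
        return self.coefficient * (1.0 - np.exp(-x / self.scale))


@dataclass(frozen=True)
class GroundTruthResponse:
    base_yield: float = 6000.0                      # kg/ha
    cultivar_effects: dict = field(default_factory=dict)
    driver_terms: tuple = ()
    noise_sd: float = 0.0                           # kg/ha
    yield_floor: float = YIELD_FLOOR


def signal_yield(row, response: GroundTruthResponse) -> float:
    """Deterministic part of the yield for one indicator row."""
    total = response.base_yield
    cultivar = row.get("Cultivar", None) if hasattr(row, "get") else None
    if cultivar is not None:
        total += response.cultivar_effects.get(cultivar, 0.0)
    for term in response.driver_terms:
        if term.indicator not in row:
            raise KeyError(f"driver indicator {term.indicator!r} missing from row")
        total += float(term.contribution(row[term.indicator]))
    return float(total)


def ground_truth_yield(row, response: GroundTruthResponse, seed: int = 0) -> float:
    """Yield = base + cultivar effect + driver terms + Normal(0, noise_sd),
    truncated at the configured floor."""
    y = signal_yield(row, response)
    if response.noise_sd > 0:
        y += float(np.random.default_rng(seed).normal(0.0, response.noise_sd))
    return max(y, response.yield_floor)


def assign_yields(table: pd.DataFrame, response: GroundTruthResponse,
                  seed: int = 0) -> pd.DataFrame:
    """Vectorized ground-truth yields for a whole indicator table."""
    sig = np.array([signal_yield(row, response) for _, row in table.iterrows()])
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, response.noise_sd, len(sig)) if response.noise_sd > 0 else 0.0
    out = table.copy()
    out["Yield"] = np.maximum(sig + noise, response.yield_floor)
    return out


def calibrate_noise_sd(table: pd.DataFrame, response: GroundTruthResponse,
                       target_r2: float) -> float:
    """Noise level giving the requested population R-squared.

    With signal variance V over the realized indicator distribution, the
    population R-squared of the true response is V / (V + noise^2); solving
    for noise gives sd = sqrt(V * (1 - R2) / R2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    sig = np.array([signal_yield(row, response) for _, row in table.iterrows()])
    v = float(np.var(sig))
    return math.sqrt(v * (1.0 - target_r2) / target_r2)


def inject_missingness(series: pd.DataFrame, rate, seed: int = 0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank cells completely at random; returns (gappy series, boolean mask).

    ``rate`` is a probability (scalar) or a per-column mapping.  The mask is
    True exactly where a value was removed, so imputation can later be scored
    against the original.
    """
    rates = ({c: float(rate) for c in series.columns}
             if np.isscalar(rate) else dict(rate))
    for c, r in rates.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"rate for {c} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = series.copy()
    mask = pd.DataFrame(False, index=series.index, columns=series.columns)
    for c in series.columns:
        r = rates.get(c, 0.0)
        if r <= 0:
            continue
        hit = rng.random(len(series)) < r
        mask[c] = hit & series[c].notna().to_numpy()
        out.loc[mask[c], c] = np.nan
    return out, mask


def generate_regime_mixture(k: int, regime_params: list[WeatherGenParams],
                            events_per_regime, seed: int = 0,
                            start_date="2010-01-01", n_days: int = 560,
                            sowing_days: int = 180,
                            cultivars: list[CultivarStageProfile] | None = None,
                            ) -> tuple[list[EventSeriesBundle], np.ndarray, pd.DataFrame]:
    """Events from k distinct weather regimes, tagged with their true regime.

    Each regime gets its own weather realization from its own parameters;
    the returned labels allow external validation of pattern clustering.
    Returns (bundles, labels, events table).
    """
    if k < 2:
        if k == 1:
            warnings.warn("single regime: recovery not identifiable", stacklevel=2)
        else:
            raise ValueError("k must be >= 1")
    if len(regime_params) != k:
        raise ValueError("need one parameter set per regime")
    if len({dataclasses.replace(p, seed=0) for p in regime_params}) < k:
        warnings.warn("identical regime parameters: recovery not identifiable",
                      stacklevel=2)
    counts = ([int(events_per_regime)] * k if np.isscalar(events_per_regime)
              else [int(c) for c in events_per_regime])
    if cultivars is None:
        cultivars = [CultivarStageProfile("CV1", 55, 36, 35)]
    seeds = np.random.SeedSequence(seed).spawn(k)
    bundles: list[EventSeriesBundle] = []
    labels: list[int] = []
    frames = []
    start = pd.Timestamp(start_date)
    for r in range(k):
        child = int(seeds[r].generate_state(1)[0] % (2 ** 31))
        params = dataclasses.replace(regime_params[r], seed=child)
        weather = generate_daily_weather(params, start, n_days)
        window = (start + pd.Timedelta(days=7),
                  start + pd.Timedelta(days=7 + sowing_days))
        ev = generate_cropping_events(weather, counts[r], cultivars, window,
                                      seed=child + 1, locality=f"regime{r}")
        ev = ev.assign(regime=r, event_id=[f"R{r}_{i:04d}" for i in range(len(ev))])
        for _, rec in ev.iterrows():
            idx = pd.date_range(rec["sowing_date"], rec["harvest_date"], freq="D")
            win = weather.loc[idx]
            bundles.append(EventSeriesBundle(
                rec["event_id"],
                {v: win[v].to_numpy() for v in ("TX", "TM", "P", "RH", "SR")},
                cultivar=rec["cultivar"]))
            labels.append(r)
        frames.append(ev)
    return bundles, np.asarray(labels), pd.concat(frames, ignore_index=True)
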