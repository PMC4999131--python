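"""Canned synthetic study conditions with known ground truth.

These builders freeze the conditions under which the pipeline is validated:
a driver-recovery design whose yields respond to a night-temperature hinge
in the reproductive stage and linearly to ripening-stage solar accumulation,
its pure-noise null twin, and a correlated-copy design for checking that
conditional importance discounts spurious correlates.  The driver choices
anchor to field knowledge: warm nights during the reproductive stage depress
rice yields gradually beyond about 22.7 deg C, and roughly 100 cal cm-2
day-1 of extra ripening-stage radiation is worth on the order of 1,000 kg
ha-1, i.e. ~0.3 kg ha-1 per accumulated cal cm-2 over a ~35-day stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import CultivarStageProfile, build_indicator_table
from .synthetic import (DriverTerm, GroundTruthResponse, WeatherGenParams,
                        assign_yields, calibrate_noise_sd,
                        generate_cropping_events, generate_daily_weather)

#: Night-temperature hinge: yields decline beyond this reproductive-stage
#: average minimum temperature (deg C).
TM_REP_BREAKPOINT = 22.7

#: kg ha-1 lost per deg C above the breakpoint.
TM_REP_HINGE_COEF = -300.0

#: kg ha-1 gained per accumulated cal cm-2 of ripening-stage radiation.
SR_RIP_LINEAR_COEF = 0.3

TRUE_DRIVERS = ("TM_Avg_REP", "SR_Accu_RIP")

DEFAULT_PROFILES = {
    "CV1": CultivarStageProfile("CV1", 55, 36, 35),
    "CV2": CultivarStageProfile("CV2", 58, 35, 33),
    "CV3": CultivarStageProfile("CV3", 52, 38, 36),
}


def default_response(noise_sd: float = 0.0,
                     cultivar_effects: dict | None = None) -> GroundTruthResponse:
    return GroundTruthResponse(
        base_yield=6000.0,
        cultivar_effects=cultivar_effects or {},
        driver_terms=(
            DriverTerm("TM_Avg_REP", "hinge", TM_REP_HINGE_COEF,
                       breakpoint=TM_REP_BREAKPOINT),
            DriverTerm("SR_Accu_RIP", "linear", SR_RIP_LINEAR_COEF),
        ),
        noise_sd=noise_sd,
    )


def indicator_table(seed: int, n_events: int = 600,
                    params: WeatherGenParams | None = None,
                    start="2010-01-01", n_days: int = 760,
                    sowing_days: int = 365) -> pd.DataFrame:
    """Indicator table (yield unset) for ``n_events`` events over fresh weather."""
    import dataclasses
    params = params or WeatherGenParams(seed=seed)
    if params.seed != seed:
        params = dataclasses.replace(params, seed=seed)
    weather = generate_daily_weather(params, start, n_days)
    window = (weather.index[10], weather.index[10 + sowing_days])
    events = generate_cropping_events(
        weather, n_events, list(DEFAULT_PROFILES.values()), window,
        seed=seed + 1)
    table, _ = build_indicator_table(events, weather, DEFAULT_PROFILES)
    return table


def balanced_response(table: pd.DataFrame, noise_sd: float = 0.0,
                      cultivar_effects: dict | None = None,
                      ) -> GroundTruthResponse:
    """Two-driver truth with the drivers balanced to equal signal variance.

    The hinge keeps its anchored breakpoint and slope; the SR coefficient is
    scaled so the linear term's realized standard deviation over the supplied
    indicator distribution matches the hinge term's.  A recovery experiment
    is only informative about *both* drivers when neither dwarfs the other;
    the anchored per-unit coefficients set the scale, the balance sets the
    ratio.
    """
    hinge = DriverTerm("TM_Avg_REP", "hinge", TM_REP_HINGE_COEF,
                       breakpoint=TM_REP_BREAKPOINT)
    hinge_sd = float(np.std(hinge.contribution(table["TM_Avg_REP"])))
    sr_sd = float(np.std(table["SR_Accu_RIP"]))
    coef = hinge_sd / sr_sd if sr_sd > 0 else SR_RIP_LINEAR_COEF
    return GroundTruthResponse(
        base_yield=6000.0,
        cultivar_effects=cultivar_effects or {},
        driver_terms=(hinge, DriverTerm("SR_Accu_RIP", "linear", coef)),
        noise_sd=noise_sd,
    )


def driver_recovery_table(seed: int, n_events: int = 600,
                          target_r2: float = 0.35) -> pd.DataFrame:
    """Events whose yields follow the two-driver truth at a known signal level.

    The two driver terms are balanced to equal realized variance and the
    noise standard deviation is solved from the signal variance so that the
    population R-squared of the true response equals ``target_r2``.
    """
    table = indicator_table(seed, n_events=n_events)
    resp0 = balanced_response(table)
    noise_sd = calibrate_noise_sd(table, resp0, target_r2)
    resp = balanced_response(table, noise_sd=noise_sd)
    return assign_yields(table, resp, seed=seed + 2)


def null_table(seed: int, n_events: int = 600,
               yield_sd: float = 900.0) -> pd.DataFrame:
    """Same indicator design with yields that are pure noise."""
    table = indicator_table(seed, n_events=n_events)
    rng = np.random.default_rng(seed + 2)
    table = table.copy()
    table["Yield"] = 6000.0 + rng.normal(0.0, yield_sd, len(table))
    return table


def correlated_copy_design(seed: int, n: int = 300, n_noise: int = 7,
                           copy_noise: float = 0.5,
                           noise_sd: float = 0.5) -> pd.DataFrame:
    """x2 is a noisy copy of the true driver x1 (r ~ 0.9); y depends on x1 only.

    Used to verify that conditional permutation importance assigns the
    spurious correlate x2 less credit than the marginal measure does.
    """
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0.0, 1.0, n)
    x2 = x1 + rng.normal(0.0, copy_noise, n)
    cols = {"x1": x1, "x2": x2}
    for i in range(n_noise):
        cols[f"z{i}"] = rng.normal(0.0, 1.0, n)
    y = 2.0 * x1 + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(cols)
    df["Yield"] = y
    return df
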