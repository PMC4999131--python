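"""Build the cropping-event indicator table from simulated inputs.

Joins each harvest record to its sowing-to-harvest weather window, splits
the cycle into the three growth stages scaled from the cultivar profile,
computes the 27 stage indicators, and applies the low-variance / outlier
cleaning.  Requires 01_simulate.py to have run.
"""

import sys
from pathlib import Path

import pandas as pd

from riceclim.events import build_indicator_table, clean_indicator_table
from riceclim.scenarios import DEFAULT_PROFILES
from riceclim.weather import derive_ta_dr

BASE = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    src = BASE / "simulated"
    weather = derive_ta_dr(pd.read_csv(src / "weather.csv", index_col=0,
                                       parse_dates=True))
    events = pd.read_csv(src / "events.csv",
                         parse_dates=["sowing_date", "harvest_date"])
    table, excluded = build_indicator_table(events, weather, DEFAULT_PROFILES)
    table, removals = clean_indicator_table(table)
    table.to_csv(BASE / "indicators.csv", index=False)
    removals.to_csv(BASE / "removals.csv", index=False)
    print(f"{len(events)} events -> {len(table)} indicator rows "
          f"({len(excluded)} window exclusions, "
          f"{(removals['kind'] == 'row').sum()} fenced rows, "
          f"{(removals['kind'] == 'column').sum()} dropped columns)")
    print(table.filter(like="_REP").describe().loc[["mean", "std"]].round(2))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
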