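"""Group cropping events by their whole daily weather patterns.

Computes DTW distances between events' standardized five-variable daily
series, clusters them hierarchically (Ward on squared distances), picks the
cluster count by the inertia-gain elbow, and compares yields across clusters
(and cultivars within clusters) with Kruskal-Wallis letter groups.
Requires 01_simulate.py to have run.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from riceclim.clustering import (cluster_yield_analysis,
                                 cultivar_within_cluster, cut_tree,
                                 hierarchical_cluster, select_k_inertia_gain)
from riceclim.dtw import (EventSeriesBundle, pairwise_distance_matrix,
                          standardize_event_series)

BASE = Path(__file__).resolve().parents[1] / "results"
N_EVENTS = 150  # DTW matrix cost grows quadratically; a subset suffices here


def main(seed: int = 1) -> None:
    src = BASE / "simulated"
    weather = pd.read_csv(src / "weather.csv", index_col=0, parse_dates=True)
    events = pd.read_csv(src / "events.csv",
                         parse_dates=["sowing_date", "harvest_date"])
    events = events.iloc[:N_EVENTS]
    bundles = []
    for _, rec in events.iterrows():
        win = weather.loc[rec["sowing_date"]:rec["harvest_date"]]
        bundles.append(EventSeriesBundle(
            rec["event_id"],
            {v: win[v].to_numpy() for v in ("TX", "TM", "P", "RH", "SR")},
            yield_kg_ha=rec["yield"], cultivar=rec["cultivar"]))
    dmat = pairwise_distance_matrix(standardize_event_series(bundles))
    Z = hierarchical_cluster(dmat)
    k = select_k_inertia_gain(Z, k_max=12)
    labels = cut_tree(Z, k)
    print(f"{len(bundles)} events -> {k} weather-pattern clusters")

    yields = np.array([b.yield_kg_ha for b in bundles])
    cultivars = np.array([b.cultivar for b in bundles])
    summary = cluster_yield_analysis(labels, yields)
    if summary.letters is not None:
        summary.table["letters"] = [
            summary.letters.letters.get(str(c), "")
            for c in summary.table["cluster"]]
    print(summary.table.round(0).to_string(index=False))
    summary.table.to_csv(BASE / "cluster_yields.csv", index=False)
    pd.DataFrame({"event_id": [b.event_id for b in bundles],
                  "cluster": labels}).to_csv(BASE / "cluster_labels.csv",
                                             index=False)
    within = cultivar_within_cluster(labels, yields, cultivars)
    for c, res in within.items():
        desc = res if isinstance(res, str) else \
            " ".join(f"{cv}:{letters}" for cv, letters in res.letters.items())
        print(f"  cluster {c}: {desc}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
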