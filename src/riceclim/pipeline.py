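"""Pipeline orchestration: configuration, simulation and end-to-end runs.

The scientific parameters live in one structured, JSON-round-trippable
config object so an analysis is auditable and reproducible from (config,
seed) alone.  ``cmd_simulate`` writes a synthetic weather/harvest dataset
with its ground-truth sidecar; ``cmd_run_all`` drives the full chain
(weather preparation, event construction, indicator table, importance
ensemble, DTW pattern clustering) and emits CSV/JSON reports plus a run
manifest with per-stage row counts.  The numbered scripts under
``analysis/`` are thin front-ends over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, dtw, importance, impute, letters, synthetic, weather
from .events import build_indicator_table, clean_indicator_table
from .forest import ForestConfig
from .scenarios import DEFAULT_PROFILES, balanced_response
from .synthetic import (WeatherGenParams, assign_yields, calibrate_noise_sd,
                        generate_cropping_events, generate_daily_weather)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_events: int = 300
    n_days: int = 760
    start_date: str = "2010-01-01"
    sowing_days: int = 365
    target_r2: float = 0.35
    cultivar_effects: dict = field(default_factory=lambda: {
        "CV1": 150.0, "CV2": 0.0, "CV3": -150.0})
    weather_params: dict = field(default_factory=dict)
    ntree: int = 100
    vi_runs: int = 10
    mtry: int | None = None
    cluster_events: int = 120
    k_max: int = 12

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def forest_config(self, seed: int) -> ForestConfig:
        return ForestConfig(ntree=self.ntree, mtry=self.mtry, seed=seed)

    def gen_params(self) -> WeatherGenParams:
        return WeatherGenParams(**{"seed": self.seed, **self.weather_params})


def _write_manifest(outdir: Path, config: PipelineConfig, stages: dict,
                    t0: float) -> dict:
    manifest = {
        "config": json.loads(config.to_json()),
        "package": "riceclim 0.1.0",
        "stages": stages,
        "wall_time_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def cmd_simulate(config: PipelineConfig, outdir) -> dict:
    """Write synthetic weather + events CSVs and the ground-truth sidecar."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.gen_params()
    wx = generate_daily_weather(params, config.start_date, config.n_days)
    window = (wx.index[10], wx.index[10 + config.sowing_days])
    events = generate_cropping_events(
        wx, config.n_events, list(DEFAULT_PROFILES.values()), window,
        seed=config.seed + 1)
    table, excluded = build_indicator_table(events, weather.derive_ta_dr(wx),
                                            DEFAULT_PROFILES)
    resp0 = balanced_response(table, cultivar_effects=config.cultivar_effects)
    noise_sd = calibrate_noise_sd(table, resp0, config.target_r2)
    resp = balanced_response(table, noise_sd=noise_sd,
                             cultivar_effects=config.cultivar_effects)
    table = assign_yields(table, resp, seed=config.seed + 2)
    events = events.merge(table[["event_id", "Yield"]], on="event_id",
                          how="left")
    events["yield"] = events.pop("Yield")

    wx.to_csv(outdir / "weather.csv", date_format="%Y-%m-%d",
              float_format="%.4f")
    events.to_csv(outdir / "events.csv", index=False, date_format="%Y-%m-%d")
    truth = {
        "noise_sd": noise_sd,
        "response": {
            "base_yield": resp.base_yield,
            "cultivar_effects": resp.cultivar_effects,
            "drivers": [asdict(t) for t in resp.driver_terms],
        },
        "weather_params": asdict(params),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    (outdir / "run.log").write_text(
        f"simulated {len(events)} events over {config.n_days} days; "
        f"{len(excluded)} excluded\n")
    stages = {"weather_days": len(wx), "events": len(events),
              "indicator_rows": len(table), "excluded_events": len(excluded)}
    return _write_manifest(outdir, config, stages, t0)


def cmd_run_all(config: PipelineConfig, outdir,
                weather_csv=None, events_csv=None) -> dict:
    """Full pipeline: prepare -> events -> importance -> clusters, with reports.

    Inputs are read from ``weather_csv``/``events_csv`` when given, else
    simulated under ``config``.  Any stage failure raises with the stage
    name; partial outputs written so far are preserved.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    stage = "simulate"
    try:
        if weather_csv is None or events_csv is None:
            cmd_simulate(config, outdir / "inputs")
            weather_csv = outdir / "inputs" / "weather.csv"
            events_csv = outdir / "inputs" / "events.csv"
        wx = pd.read_csv(weather_csv, index_col=0, parse_dates=True)
        events = pd.read_csv(events_csv,
                             parse_dates=["sowing_date", "harvest_date"])
        stages["weather_days"] = len(wx)
        stages["events_in"] = len(events)

        stage = "prepare_weather"
        wx, qc_report = weather.qc_daily(wx)
        if wx[["TX", "TM", "P"]].isna().any().any():
            wx_tmp, _ = impute.impute_var_temperature_precip(
                wx[["TX", "TM", "P"]], seed=config.seed + 5)
            wx[["TX", "TM", "P"]] = wx_tmp
        for v in ("RH", "SR"):
            if wx[v].isna().any():
                wx[v], _ = impute.impute_forest_rh_sr(
                    wx[v], wx[["TM", "TX", "P"]], ntree=100,
                    seed=config.seed + 6)
        wx = weather.derive_ta_dr(wx.dropna())
        stages["weather_days_prepared"] = len(wx)

        stage = "build_events"
        table, excluded = build_indicator_table(events, wx, DEFAULT_PROFILES)
        table, removal_log = clean_indicator_table(table)
        removal_log.to_csv(outdir / "removals.csv", index=False)
        stages["events_excluded"] = len(excluded)
        stages["indicator_rows"] = len(table)
        table.to_csv(outdir / "indicators.csv", index=False)

        stage = "vi_analysis"
        ens = importance.run_vi_ensemble(
            table, config=config.forest_config(config.seed + 10),
            runs=config.vi_runs, seed=config.seed + 10)
        ens.scaled_matrix.to_csv(outdir / "vi_runs.csv", index=False)
        final = ens.final_vi.sort_values(ascending=False)
        groups = ens.letter_groups()
        pd.DataFrame({"final_vi": final,
                      "letters": [groups.letters[k] for k in final.index]}
                     ).to_csv(outdir / "vi_final.csv")
        stages["vi_runs"] = len(ens.runs)
        stages["mean_r2"] = round(float(ens.r2.mean()), 4)

        stage = "cluster_patterns"
        sub = events.iloc[:config.cluster_events]
        bundles = []
        for _, rec in sub.iterrows():
            idx = pd.date_range(rec["sowing_date"], rec["harvest_date"],
                                freq="D")
            if not idx.isin(wx.index).all():
                continue
            win = wx.loc[idx]
            bundles.append(dtw.EventSeriesBundle(
                rec["event_id"],
                {v: win[v].to_numpy() for v in ("TX", "TM", "P", "RH", "SR")},
                yield_kg_ha=rec["yield"], cultivar=rec["cultivar"]))
        std = dtw.standardize_event_series(bundles)
        dmat = dtw.pairwise_distance_matrix(std)
        np.savetxt(outdir / "distance_matrix.csv", dmat, delimiter=",")
        Z = clustering.hierarchical_cluster(dmat)
        k = clustering.select_k_inertia_gain(Z, k_max=config.k_max)
        labels = clustering.cut_tree(Z, k)
        yields = np.array([b.yield_kg_ha for b in bundles])
        cultivars = np.array([b.cultivar for b in bundles])
        summary = clustering.cluster_yield_analysis(labels, yields)
        summary.table.to_csv(outdir / "cluster_yields.csv", index=False)
        pd.DataFrame({"event_id": [b.event_id for b in bundles],
                      "cluster": labels}).to_csv(outdir / "cluster_labels.csv",
                                                 index=False)
        within = clustering.cultivar_within_cluster(labels, yields, cultivars)
        stages["clusters"] = int(k)
        stages["clustered_events"] = len(bundles)
        stages["within_cluster_comparisons"] = len(within)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return _write_manifest(outdir, config, stages, t0)
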