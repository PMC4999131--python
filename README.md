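# riceclim

Weather–yield analysis for tropical rice from observational data: build
*cropping events* (one harvest record joined to the daily weather it
experienced from sowing to harvest), summarize each event into 27
growth-stage climatic indicators, identify the limiting climatic factors
with an ensemble of conditional-inference regression forests and
conditional permutation importance, and group events by their whole daily
weather patterns with dynamic-time-warping (DTW) clustering to see what
yields each weather regime allowed.

The package is aimed at agronomists and biostatisticians working with
commercial harvest records and station weather — data that are noisy,
collinear and nonlinear, which is why the toolchain is built around
association-test forests rather than linear models.  Since such records are
rarely shareable, `riceclim` ships a synthetic weather/event/yield
generator with known ground truth, and the entire pipeline is validated by
recovering that truth.

## The method in brief

For each event the cycle is split into the vegetative, reproductive and
ripening stages (cultivar reference durations scaled to the actual cycle),
and per stage the indicators TX_Avg, TM_Avg, TA_Avg, DR_Avg, TX_{35,37,31}_Freq,
P_Accu, P_10_Freq, RH_Avg, SR_Accu are computed.  A conditional-inference
forest regresses yield on the indicators: at each node the split variable
is chosen by the smallest association-test p-value (standardized linear
statistic, Bonferroni-stopped at α = 0.05), which removes the selection
bias of impurity-based trees.  Importance is *conditional* permutation
importance — a predictor is permuted only within the strata its correlated
covariates induce through the tree's own split points — so a predictor is
credited for its own contribution, not for what it borrows through
correlation.  Importances from an ensemble of runs are normalized, scaled
by each run's R², averaged, and compared with Kruskal–Wallis letter groups;
partial-dependence profiles show the shape of each response (e.g. a yield
decline beyond a night-temperature threshold).  Separately, events are
compared through the DTW distance summed over their five standardized
daily series, clustered with Ward-type agglomeration, the cluster count
picked by the inertia-gain elbow, and yields compared across clusters and
cultivars within clusters.

Weather preparation utilities cover station screening (distance/altitude),
hourly→daily aggregation with the strict 80% completeness rule, WMO-style
plausibility QC, Angstrom–Prescott solar radiation from sunshine duration,
series merging, VAR-based gap filling of temperatures/precipitation and
forest-based filling of humidity/radiation.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data (seed 1):

```
$ python analysis/01_simulate.py 1
wrote .../results/simulated
  weather days : 760
  events       : 300 (0 excluded at window attachment)
  indicator rows: 300

$ python analysis/03_build_events.py 1
300 events -> 300 indicator rows (0 window exclusions, 0 fenced rows, 0 dropped columns)

$ python analysis/04_variable_importance.py 1
ensemble of 20 forests, mean R2 = 0.296 (sd 0.005)
top indicators (scaled importance, letter group):
  Cultivar           0.0770  a
  TM_Avg_REP         0.0666  a
  TA_Avg_REP         0.0490  a
  SR_Accu_RIP        0.0228  a
  TX_Avg_REP         0.0186  ab
  TM_Avg_RIP         0.0132  abc
  TA_Avg_RIP         0.0061  bcd
  TM_Avg_VEG         0.0058  bcde
partial dependence of TM_Avg_REP: estimated breakpoint 22.53 deg C (truth: 22.7),
slope above -185 kg/ha per deg C
```

The simulation's true yield response has three components: cultivar
effects, a hinge on the reproductive-stage night temperature (flat below
22.7 °C, −300 kg·ha⁻¹ per extra °C above it), and ripening-stage solar
accumulation.  The ensemble recovers exactly this structure: cultivar and
the two climatic drivers head the ranking (the near-duplicate TA_Avg_REP
rides along with TM_Avg_REP — they correlate at ~0.95 by construction),
the model R² of 0.30 tracks the simulated signal level, and the
partial-dependence breakpoint lands within 0.2 °C of the truth.

```
$ python analysis/05_cluster_patterns.py 1
150 events -> 10 weather-pattern clusters
 cluster  n   mean  median    sd letters
       1  9 8113.0  8189.0 481.0       a
       9 14 8078.0  8081.0 243.0       a
       ...
       4 13 7815.0  7748.0 305.0       b
       8 14 7686.0  7614.0 396.0       b
```

Clusters sharing a letter do not differ significantly in yield at the 5%
level; here the best and worst weather patterns differ by roughly
500 kg·ha⁻¹.  `analysis/02_prepare_weather.py` demonstrates the gap-filling
chain on a series with 10% of cells deleted (VAR fill of TX/TM recovers the
deleted values at r ≈ 0.83–0.88; forest fill of RH/SR at r ≈ 0.76–0.86).

`docs/methods.md` documents the models, parameter choices, and what the
synthetic validation does and does not show.

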