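# Methods

`riceclim` implements a data-driven weather–yield analysis for tropical
rice: daily station weather is prepared into complete locality series,
joined to commercial harvest records to form *cropping events*, summarized
into growth-stage climatic indicators, and analyzed two ways — an ensemble
of conditional-inference regression forests with conditional permutation
importance (which indicators limit yield, and how), and DTW-based
hierarchical clustering of whole daily weather patterns (which weather
regimes occurred, and what yields they allowed).  Because the observational
data such a study runs on are proprietary, the package ships a synthetic
generator with known ground truth, and every stage is validated against
that truth.

## The analysis unit

A cropping event is one field's sowing-to-harvest record joined to the
daily weather over exactly that period.  When the sowing date is missing it
is back-dated from the harvest by the locality's typical cycle length
(126 days irrigated, 128 rainfed; configurable).  The cycle is split into
the vegetative (VEG), reproductive (REP) and ripening (RIP) stages by
scaling cultivar-specific reference durations (defined on a 126-day
reference cycle) to the actual cycle with largest-remainder rounding, so
stage lengths always sum exactly to the cycle.  Windows include both the
sowing and harvest day; a day belongs to exactly one stage via half-open
date intervals, with the harvest day attached to RIP.

Per stage, nine indicators: mean TX, TM, TA=(TX+TM)/2, DR=TX−TM; the
frequency of days with TX strictly above 35/37/31 °C (VEG/REP/RIP —
stage-specific sterility-relevant thresholds); accumulated precipitation;
the frequency of days with strictly more than 10 mm; mean RH; and
accumulated solar radiation (cal·cm⁻², 1 MJ·m⁻² = 23.884 cal·cm⁻²).
Frequencies are proportions of stage days.  Events with cycles outside
[60, 200] days, coverage gaps, fenced outliers (outside median ± 3×IQR per
locality, configurable) or near-constant predictors are removed with
logged reasons.

## Weather preparation

Stations are screened by great-circle distance to the crops (< 10 km,
strict) and altitude (± 50 m, inclusive).  Hourly records become daily
values only when strictly more than 80% of the day's hours are valid
(TX = max, TM = min, P and SR = sum, RH = mean).  Daily QC flags and blanks
out-of-range values (tropical-plausible defaults, configurable),
TM > TX days (both temperatures blanked), and ≥ 5-day flatlines of
temperature or humidity.  Stations with complementary recording periods are
merged day-wise, primary first, with conflicts beyond tolerance (2 °C
temperature, 20% precipitation) logged.

Where only sunshine duration is recorded, solar radiation comes from the
Angstrom–Prescott relation SR = (a + b·n/N)·Ra with the FAO-recommended
defaults a = 0.25, b = 0.50 and the standard daily extraterrestrial
radiation Ra and daylength N (inverse relative Earth–Sun distance, solar
declination, sunset hour angle; latitudes beyond ±66.5° rejected).

Gap filling is two-tier.  Temperatures and precipitation: a VAR(1) on
deseasonalized anomalies (smoothed day-of-year climatology evaluated on the
*full* index; precipitation on the log1p scale), fitted by least squares on
**consecutive** complete rows only — compacting a gapped series before an
autoregressive fit mixes lags and attenuates the coefficients.  Gaps are
filled by the average of forward and backward one-step conditional means,
with the missing components of a day additionally conditioned on its
observed components through the innovation covariance, iterated three
sweeps so gap runs converge.  The fill is deterministic by default;
adding seeded innovation noise is opt-in.  Humidity and solar radiation: a
regression forest (800 trees, 2 candidate predictors per node) trained on
the days where the target is observed, with TM/TX/P as predictors; fills
are clipped to [0, 100] % (RH) or floored just above zero (SR).  Imputation
never alters an observed cell, and the imputed mask is returned for
scoring.

## Conditional-inference forests and importance

Trees are grown on bootstrap samples.  At each node, `mtry` candidate
predictors are drawn; the split **variable** is the candidate with the
smallest association-test p-value — the permutation-null z-score of the
linear statistic between predictor and response (maximum over level
indicators for categoricals) — and the node stops splitting when the
Bonferroni-adjusted minimum p-value exceeds `alpha_split` (0.05) or the
node is smaller than `minsplit` (20).  The split **point** maximizes the
standardized two-sample statistic subject to `minbucket` (7).  This
separation of variable and cutpoint selection removes the variable-selection
bias of impurity-based forests, and the significance stop acts as built-in
regularization: training R² tracks the population signal closely (near zero
on pure-noise responses), which is why the package uses training R² as the
performance weight below; the out-of-bag R² is also provided and is the
better generalization estimate, but its negative excursions under the null
would degenerate the importance scaling.

Importance is conditional permutation importance: per tree, a predictor is
permuted only within the cells that the tree's own split points on
correlated covariates (absolute Spearman correlation > 0.2, configurable)
induce on the out-of-bag samples, and the increase in OOB MSE is averaged
over trees.  Permuting within these strata preserves the predictor's
relationship to its correlates and therefore measures its *own*
contribution; the classic marginal measure is also available.  Negative
importances are retained.

Because single-forest rankings are unstable, importance is reported from an
ensemble of independently seeded runs (default 100; the validation suite
uses 20): per run, raw importances are normalized by their sum and scaled
by the run's R², so better-adjusted models carry more weight; final scores
are per-predictor means over runs.  Runs with a non-positive importance sum
get the uninformative uniform vector; runs with R² ≤ 0 contribute zero.
Tables larger than 500 rows switch to the subsampling protocol: 100
independently drawn subsets of 400 distinct rows, one forest per subset.
Importance distributions over runs are compared with a Kruskal–Wallis
letter display (below).  Per-cultivar models run on every cultivar with
strictly more than 100 events, without the cultivar column.

Partial dependence forces one predictor across a 40-point quantile grid
(1st–99th percentile) and averages predictions over all rows.  Profiles
from a handful of seeds are averaged before interpretation.  The breakpoint
of a threshold-type response is estimated as the knot of the best-fitting
flat-base hinge `a + c·max(0, x − t)` on a uniform re-gridding of the
profile: for a flat-then-sloped response this knot is the maximum-curvature
point of the underlying trend, and the matched two-parameter form is robust
to the step noise and mild convexity of a forest profile (a direct
second-derivative variant is available and documented as noisier).

## Letter display

Groups are compared on pooled midranks: Kruskal–Wallis omnibus, then
pairwise mean-rank differences against their tie-corrected
normal-approximation null standard error (Dunn's criterion), by default
without multiplicity correction — the per-comparison 5% convention of
agronomic reporting — with Bonferroni available.  Letters are maximal runs
of mutually non-significant items in decreasing mean-rank order, absorbed
when nested, so a shared letter always certifies a non-significant
difference.

## Weather-pattern clustering

Events are compared through their whole daily series.  Each variable is
pooled-z-scored across all days of all events (zero-variance variables
dropped), and the distance between two events is the equal-weighted sum of
univariate DTW distances over TX, TM, P, RH, SR ("independent" multivariate
DTW; a "dependent" variant with Euclidean day-vector cost is provided for
sensitivity analysis).  DTW uses absolute-difference local cost, symmetric
steps, boundary anchoring and no window, so events of different cycle
lengths compare naturally and short heat or drought spells still count.

Agglomeration runs Lance–Williams updates on squared distances (Ward-type,
so merge heights read as inertia increases; average and complete linkage
selectable).  The cluster count maximizes the elbow ratio H(k)/H(k+1),
where H(k) is the height of the merge that destroys the k-cluster solution
— a good k is cheap to build and expensive to destroy; ties pick the
smallest k and a flat dendrogram falls back to k_min with a warning.
Cluster yields are summarized (n, mean, median, sd, in decreasing median
order) and compared with the letter display; clusters with fewer than 10
events are excluded from the within-cluster cultivar comparison, in which
cultivars with fewer than 5 events are pooled out.

## The synthetic generator

The generator emulates a tropical lowland station, calibrated once to the
observed variability envelope of the study regions: maximum temperature is
a small seasonal harmonic (0.8 °C amplitude — tropical temperatures are
nearly constant seasonally) plus an AR(1) anomaly (lag-1 0.7, sd 1.8 °C)
around 32 °C; the diurnal range (mean 9.5 °C) co-varies with the TX anomaly
(gain 0.7 — clear hot days have larger diurnal ranges, so TM varies *less*
than TX, matching observed CVs of ~0.07 for TX vs ~0.04–0.05 for TM), has
its own AR(1) spell persistence and shrinks on wet days; TM = TX − DR, so
TM < TX holds by construction.  Precipitation is a two-state Markov chain
(stationary wet probability 0.45, persistence 0.6) with gamma amounts and a
seasonally modulated, optionally bimodal wet probability; humidity is
inversely coupled to the diurnal range and boosted on wet days, clipped to
[0, 100]; solar radiation is a clear-sky value attenuated on wet days,
kept positive.  One integer seed is split across variables with
`SeedSequence`, so adding a variable never perturbs earlier draws.

Yields follow a known response over the indicators: base 6,000 kg·ha⁻¹,
optional cultivar effects, driver terms (linear, hinge, saturating) and
Gaussian noise, truncated at a 500 kg·ha⁻¹ floor.  The validation scenario
uses two drivers: a hinge on TM_Avg_REP with breakpoint 22.7 °C and slope
−300 kg·ha⁻¹·°C⁻¹ (warm nights in the reproductive stage depress yield),
and a positive linear term in SR_Accu_RIP (~0.3 kg·ha⁻¹ per cal·cm⁻² as the
order-of-magnitude anchor).  In the recovery scenario the two terms are
balanced to equal realized variance — a recovery experiment is only
informative about both drivers when neither dwarfs the other — and the
noise sd is solved from the realized signal variance so the population R²
is exactly the target (0.35 in the standard scenario, 0.95 in the
strong-signal variant used for response-shape checks).

What the generator does *not* emulate: spatial structure across stations,
interannual (ENSO-type) variability, instrument error and inhomogeneities,
biotic stresses, or management variation.  Passing tests therefore show the
pipeline recovers known structure under realistic marginals and
correlations — not that real observational data are this well behaved.

## Validation scale and known limitations

The validation suite runs reduced settings (ntree 200, 20 runs, 20
replicates of 600 events; 120-tree forests for profile averaging) — chosen
as the smallest sizes at which the ensemble statistics stabilize; the
package defaults (ntree 2000, 100 runs) remain the recommended analysis
settings.

Two honest limitations surfaced by the validation suite, both documented
rather than patched:

- Under strong collinearity the conditional importance cannot always
  separate a true driver from a near-duplicate: TA is *defined* from TM, so
  their stage means correlate at ~0.9–0.96, conditioning suppresses both
  symmetrically, and in roughly 15% of replicates at population R² 0.35 the
  hinge driver ranks just below a looser correlate.  The affected
  replicates are stable under ensemble re-seeding, i.e. this is a property
  of those realizations, not estimator noise.
- Under the null (yields independent of weather) forests rarely split, so
  per-run normalized importances are heavy-tailed across predictors and the
  max/median ratio of final importances is an unstable diagnostic; the mean
  ensemble R² (~0.01–0.02) is the reliable null indicator.
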