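"""Permutation variable importance, run ensembles and partial dependence.

A single forest's importance ranking is unstable, so importance is measured
on an ensemble of independently seeded forests: per run the raw conditional
permutation importances are normalized (divided by their sum) and scaled by
the run's out-of-bag R-squared, so well-adjusted models carry more weight;
final scores are the per-predictor means over runs.  Conditional permutation
shuffles a predictor only within the strata its correlated covariates induce
(through the tree's own split points), which separates a predictor's own
contribution from what it borrows through correlation.

On large tables (n above ``subsample_trigger``) each run is trained on an
independently drawn subset of ``subset_size`` rows without replacement,
which bounds the cost of the conditional importance grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import INDICATOR_NAMES
from .forest import ForestConfig, ForestModel, _partial_profile, \
    _permutation_vi, encode_matrix, fit_cif, insample_r2, oob_r2
from .letters import LetterGrouping, kw_letter_grouping


def _conditioning_sets(Xm: np.ndarray, is_cat: np.ndarray,
                       threshold: float) -> np.ndarray:
    """cond[j, k] True when |Spearman rho(j, k)| > threshold (continuous k)."""
    p = Xm.shape[1]
    if p == 1:
        return np.zeros((1, 1), np.bool_)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        rho = stats.spearmanr(Xm).statistic
    rho = np.atleast_2d(np.nan_to_num(rho))
    cond = np.abs(rho) > threshold
    np.fill_diagonal(cond, False)
    cond[:, is_cat] = False  # strata are built from continuous split points
    return np.ascontiguousarray(cond)


def conditional_permutation_vi(model: ForestModel, X=None, y=None,
                               cond_threshold: float = 0.2,
                               seed: int = 0) -> np.ndarray:
    """Raw conditional permutation importances (OOB MSE increase per predictor).

    Negative values (predictors whose permutation accidentally helps) are
    retained.  ``cond_threshold`` is the absolute Spearman correlation above
    which a covariate joins the conditioning grid; 0 disables conditioning
    for that pair.
    """
    Xm = model._Xm if X is None else encode_matrix(X, model.feature_names,
                                                   model.categories)
    yv = model._y if y is None else np.asarray(y, dtype=np.float64)
    cond = _conditioning_sets(Xm, model.is_cat, cond_threshold)
    return _permutation_vi(*model._tree_arrays(), model.is_cat, Xm, yv,
                           model.inbag, cond, int(seed) % (2 ** 31))


def marginal_permutation_vi(model: ForestModel, X=None, y=None,
                            seed: int = 0) -> np.ndarray:
    """Unconditioned permutation importance (the classic marginal measure)."""
    Xm = model._Xm if X is None else encode_matrix(X, model.feature_names,
                                                   model.categories)
    yv = model._y if y is None else np.asarray(y, dtype=np.float64)
    p = Xm.shape[1]
    cond = np.zeros((p, p), np.bool_)
    return _permutation_vi(*model._tree_arrays(), model.is_cat, Xm, yv,
                           model.inbag, cond, int(seed) % (2 ** 31))


@dataclass
class VIRun:
    run_id: int
    raw: np.ndarray
    normalized: np.ndarray
    r_squared: float
    scaled: np.ndarray
    degenerate: bool = False


@dataclass
class VIEnsembleResult:
    predictors: list[str]
    runs: list[VIRun]
    subsampled: bool
    subset_rows: list[np.ndarray] = field(default_factory=list)

    @property
    def r2(self) -> np.ndarray:
        return np.array([r.r_squared for r in self.runs])

    @property
    def scaled_matrix(self) -> pd.DataFrame:
        return pd.DataFrame([r.scaled for r in self.runs],
                            columns=self.predictors)

    @property
    def final_vi(self) -> pd.Series:
        return self.scaled_matrix.mean(axis=0).rename("final_vi")

    def top(self, k: int = 3) -> list[str]:
        return list(self.final_vi.sort_values(ascending=False).index[:k])

    def letter_groups(self, alpha: float = 0.05) -> LetterGrouping:
        samples = {c: self.scaled_matrix[c].to_numpy() for c in self.predictors}
        return kw_letter_grouping(samples, alpha=alpha)


def _one_run(table, predictors, response, config, cond_threshold, run_seed,
             run_id) -> VIRun:
    X = table[predictors]
    y = table[response].to_numpy(dtype=float)
    model = fit_cif(X, y, config=config)
    r2 = insample_r2(model)
    raw = conditional_permutation_vi(model, cond_threshold=cond_threshold,
                                     seed=run_seed + 1)
    s = raw.sum()
    degenerate = not np.isfinite(s) or s <= 0
    if degenerate:
        normalized = np.full(len(raw), 1.0 / len(raw))
    else:
        normalized = raw / s
    # runs without explanatory power (R^2 <= 0) contribute zero importance
    scaled = normalized * max(r2, 0.0)
    return VIRun(run_id, raw, normalized, r2, scaled, degenerate)


def run_vi_ensemble(table: pd.DataFrame, config: ForestConfig | None = None,
                    runs: int = 100, subsample_trigger: int = 500,
                    subsets: int = 100, subset_size: int = 400,
                    seed: int = 0, predictors: list[str] | None = None,
                    response: str = "Yield",
                    cond_threshold: float = 0.2) -> VIEnsembleResult:
    """Ensemble of independently seeded forests with scaled importances.

    With n <= ``subsample_trigger`` each of ``runs`` forests sees the full
    table; otherwise ``subsets`` subsets of ``subset_size`` distinct rows are
    drawn independently (a row may appear in several subsets) and one forest
    is trained per subset.
    """
    config = config or ForestConfig()
    if predictors is None:
        predictors = [c for c in table.columns
                      if c in INDICATOR_NAMES or c == "Cultivar"]
    n = len(table)
    if n < 50:
        raise ValueError(f"need at least 50 rows, got {n}")
    rng = np.random.default_rng(seed)
    subsampled = n > subsample_trigger
    n_runs = subsets if subsampled else runs
    if subsampled and subset_size > n:
        warnings.warn(f"subset_size lowered from {subset_size} to {n}",
                      stacklevel=2)
        subset_size = n
    result = VIEnsembleResult(list(predictors), [], subsampled)
    for r in range(n_runs):
        run_seed = int(rng.integers(2 ** 31 - 2))
        if subsampled:
            rows = np.sort(rng.choice(n, size=subset_size, replace=False))
            sub = table.iloc[rows]
            result.subset_rows.append(rows)
        else:
            sub = table
        run_config = ForestConfig(ntree=config.ntree, mtry=config.mtry,
                                  alpha_split=config.alpha_split,
                                  minsplit=config.minsplit,
                                  minbucket=config.minbucket, seed=run_seed)
        result.runs.append(_one_run(sub, predictors, response, run_config,
                                    cond_threshold, run_seed, r))
    return result


def per_cultivar_models(table: pd.DataFrame, min_n: int = 100,
                        config: ForestConfig | None = None,
                        **ensemble_kwargs) -> tuple[dict, dict]:
    """Run the VI ensemble separately per cultivar with n > ``min_n`` (strict).

    The cultivar column is excluded from the predictors within each subset.
    Returns (results keyed by cultivar, skipped cultivars with their counts).
    """
    if "Cultivar" not in table.columns:
        raise ValueError("table has no Cultivar column")
    preds = [c for c in table.columns if c in INDICATOR_NAMES]
    results: dict = {}
    skipped: dict = {}
    for cultivar, sub in table.groupby("Cultivar", sort=True):
        if len(sub) > min_n:
            results[cultivar] = run_vi_ensemble(
                sub.reset_index(drop=True), config=config, predictors=preds,
                **ensemble_kwargs)
        else:
            skipped[cultivar] = len(sub)
    return results, skipped


@dataclass
class PartialDependenceProfile:
    predictor: str
    grid: np.ndarray
    profile: np.ndarray
    rug: np.ndarray

    def slope(self, lo: float | None = None, hi: float | None = None) -> float:
        """Least-squares slope of the profile over a grid interval."""
        m = np.ones(len(self.grid), bool)
        if lo is not None:
            m &= self.grid >= lo
        if hi is not None:
            m &= self.grid <= hi
        if m.sum() < 2:
            raise ValueError("interval contains fewer than 2 grid points")
        return float(np.polyfit(self.grid[m], self.profile[m], 1)[0])


def partial_dependence(model: ForestModel, X=None, predictor: str = "",
                       grid_size: int = 40) -> PartialDependenceProfile:
    """Mean model prediction with one predictor forced across a quantile grid.

    The grid spans the 1st to 99th percentile of the observed predictor; at
    each grid value the predictor is overridden for every row and the
    predictions averaged.
    """
    Xm = model._Xm if X is None else encode_matrix(X, model.feature_names,
                                                   model.categories)
    if predictor not in model.feature_names:
        raise KeyError(predictor)
    j = model.feature_names.index(predictor)
    if model.is_cat[j]:
        raise ValueError("partial dependence grid requires a continuous predictor")
    xj = Xm[:, j]
    if np.ptp(xj) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    grid = np.unique(np.quantile(xj, np.linspace(0.01, 0.99, grid_size)))
    profile = _partial_profile(*model._tree_arrays()[:6], model.is_cat, Xm, j,
                               np.ascontiguousarray(grid))
    return PartialDependenceProfile(predictor, grid, profile, xj.copy())


def average_profiles(profiles: list[PartialDependenceProfile],
                     ) -> PartialDependenceProfile:
    """Average several models' profiles for one predictor onto a common grid.

    A single forest's partial dependence is noticeably seed-dependent;
    averaging a handful of independently seeded forests stabilizes the shape
    the same way the run ensemble stabilizes importances.
    """
    names = {p.predictor for p in profiles}
    if len(names) != 1:
        raise ValueError("profiles belong to different predictors")
    grid = profiles[0].grid
    avg = np.mean([np.interp(grid, p.grid, p.profile) for p in profiles],
                  axis=0)
    return PartialDependenceProfile(profiles[0].predictor, grid, avg,
                                    profiles[0].rug)


def estimate_breakpoint(profile: PartialDependenceProfile,
                        method: str = "hinge", n_uniform: int = 120,
                        trim_frac: float = 0.05, smooth_window: int = 5,
                        edge_trim: int = 3) -> float:
    """Locate the point where the profile's slope changes most abruptly.

    ``method="hinge"`` (default) interpolates the profile onto a uniform
    grid (so each interval of the predictor counts equally, not each data
    quantile) and returns the knot of the best-fitting flat-base hinge
    ``a + c * max(0, x - t)`` with free sign of ``c``.  For a response that is constant up to a threshold and sloped beyond it,
    this knot is the maximum-curvature point of the underlying trend, and
    the matched two-parameter form is robust to the step noise and mild
    convexity of a forest profile.  ``method="curvature"`` instead returns
    the largest |second derivative| of the moving-average-smoothed profile
    on the original grid, ignoring ``edge_trim`` points at each end.
    """
    g, y = profile.grid, profile.profile
    if len(g) < 2 * edge_trim + 5:
        raise ValueError("profile too short for breakpoint estimation")
    if method == "hinge":
        gu = np.linspace(g[0], g[-1], n_uniform)
        yu = np.interp(gu, g, y)
        lo, hi = int(n_uniform * trim_frac), int(n_uniform * (1 - trim_frac))
        best_t, best_sse = float(gu[lo]), np.inf
        for t in gu[lo:hi]:
            h = np.maximum(0.0, gu - t)
            design = np.column_stack([np.ones(n_uniform), h])
            beta, _, _, _ = np.linalg.lstsq(design, yu, rcond=None)
            sse = float(np.sum((yu - design @ beta) ** 2))
            if sse < best_sse:
                best_sse, best_t = sse, float(t)
        return best_t
    if method == "curvature":
        k = max(1, smooth_window)
        kern = np.ones(k) / k
        ys = np.convolve(np.pad(y, (k // 2, k - 1 - k // 2), mode="edge"),
                         kern, mode="valid")
        d1 = np.gradient(ys, g)
        d2 = np.gradient(d1, g)
        inner = slice(edge_trim, len(g) - edge_trim)
        i = int(np.argmax(np.abs(d2[inner]))) + edge_trim
        return float(g[i])
    raise ValueError(f"unknown method {method!r}")
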