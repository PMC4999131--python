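"""Gap filling of daily weather series.

Two complementary fillers mirror common station practice: temperatures and
precipitation are filled by a vector-autoregressive model on deseasonalized
anomalies (precipitation through a log1p transform), with a
forward/backward conditional-mean pass so both neighbours of a gap inform
the estimate; humidity and solar radiation are filled by a regression forest
trained on the temperature/precipitation columns (800 trees, 2 candidate
predictors per node by default).

The fill is deterministic by default (conditional expectation); a seeded
stochastic fill adding the model's residual noise is opt-in.  Observed cells
are never altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

MIN_COMPLETE_DAYS = 60
MIN_FOREST_DAYS = 100


class _VARFit:
    """VAR(p) fitted by least squares on *consecutive* complete rows only.

    A gapped daily series must not be compacted before fitting: regressing a
    complete row on the previous complete row mixes lags and attenuates the
    autoregressive coefficients.  Here a row enters the design only when it
    and its p predecessors are all complete.
    """

    def __init__(self, data: np.ndarray, complete: np.ndarray, order: int):
        n, k = data.shape
        rows = []
        targets = []
        for t in range(order, n):
            if complete[t] and all(complete[t - lag] for lag in range(1, order + 1)):
                rows.append(np.concatenate(
                    [[1.0]] + [data[t - lag] for lag in range(1, order + 1)]))
                targets.append(data[t])
        if len(rows) < MIN_COMPLETE_DAYS:
            raise ValueError(
                f"only {len(rows)} consecutive complete rows; "
                f"need >= {MIN_COMPLETE_DAYS}")
        design = np.asarray(rows)
        Y = np.asarray(targets)
        self.params, _, _, _ = np.linalg.lstsq(design, Y, rcond=None)
        self.resid = Y - design @ self.params


def _smoothed_climatology(col: pd.Series, target_index: pd.DatetimeIndex,
                          window: int = 15) -> pd.Series:
    """Day-of-year climatology (circularly smoothed), mapped onto any index.

    Computed from the observed days of ``col`` but evaluated on
    ``target_index``, so gap days get their proper seasonal value.
    """
    obs = col.dropna()
    doy_profile = obs.groupby(obs.index.dayofyear).mean()
    doy_profile = doy_profile.reindex(range(1, 367)).interpolate(
        limit_direction="both")
    pad = window // 2
    wrapped = pd.concat([doy_profile.iloc[-pad:], doy_profile,
                         doy_profile.iloc[:pad]])
    smooth = wrapped.rolling(window, center=True, min_periods=1).mean()
    profile = smooth.iloc[pad:pad + 366].to_numpy()
    return pd.Series(profile[target_index.dayofyear - 1], index=target_index)


def impute_var_temperature_precip(series: pd.DataFrame, order: int = 1,
                                  seed: int = 0, stochastic: bool = False,
                                  n_sweeps: int = 3,
                                  columns: tuple = ("TX", "TM", "P"),
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill TM/TX/P gaps with a VAR on deseasonalized anomalies.

    Anomalies (value minus smoothed day-of-year climatology; precipitation on
    the log1p scale) are modelled with a VAR(``order``) fitted on complete
    rows.  Gaps are filled by averaging the forward prediction from the
    previous day and the backward prediction from the next day (a backward
    VAR fitted on the reversed series), iterated ``n_sweeps`` times so runs
    of consecutive gaps converge.  TM/TX consistency is enforced afterwards
    (swap and flag).  Returns (filled series, imputed mask).
    """
    cols = [c for c in columns if c in series.columns]
    if not cols:
        raise ValueError("none of the requested columns present")
    raw = series[cols].copy()
    missing = raw.isna()
    complete = (~missing).all(axis=1)
    if int(complete.sum()) < MIN_COMPLETE_DAYS:
        raise ValueError(
            f"only {int(complete.sum())} complete days; need >= {MIN_COMPLETE_DAYS}")

    work = raw.copy()
    if "P" in work.columns:
        work["P"] = np.log1p(work["P"].clip(lower=0.0))
    clim = pd.DataFrame({c: _smoothed_climatology(work[c], work.index)
                         for c in cols})
    anom = work - clim

    data = anom.to_numpy()
    comp = complete.to_numpy()
    fwd = _VARFit(data, comp, order)
    bwd = _VARFit(data[::-1], comp[::-1], order)

    filled = anom.fillna(0.0).to_numpy()
    miss = missing.to_numpy()
    n = len(filled)
    k = filled.shape[1]
    rng = np.random.default_rng(seed)
    fp = fwd.params  # (1 + order*k, k): intercept then lag coefficients
    bp = bwd.params
    sigma = np.atleast_2d(np.cov(fwd.resid, rowvar=False))
    for _ in range(n_sweeps):
        preds = np.full_like(filled, np.nan)
        for t in range(n):
            acc = np.zeros(k)
            c = 0
            if t - order >= 0:
                x = np.concatenate([filled[t - lag] for lag in range(1, order + 1)])
                acc += fp[0] + x @ fp[1:]
                c += 1
            if t + order < n:
                x = np.concatenate([filled[t + lag] for lag in range(1, order + 1)])
                acc += bp[0] + x @ bp[1:]
                c += 1
            if c == 0:
                continue
            mean_t = acc / c
            mrow = miss[t]
            if mrow.any() and not mrow.all():
                # condition the missing components on the same-day observed
                # ones through the innovation covariance
                o = ~mrow
                soo = sigma[np.ix_(o, o)]
                smo = sigma[np.ix_(mrow, o)]
                try:
                    gain = smo @ np.linalg.inv(soo)
                    mean_t = mean_t.copy()
                    mean_t[mrow] += gain @ (filled[t][o] - mean_t[o])
                except np.linalg.LinAlgError:
                    pass
            preds[t] = mean_t
        upd = miss & np.isfinite(preds)
        filled[upd] = preds[upd]
    if stochastic:
        resid_sd = np.std(fwd.resid, axis=0)
        noise = rng.normal(0.0, 1.0, filled.shape) * resid_sd
        filled[miss] += noise[miss]

    out_anom = pd.DataFrame(filled, index=anom.index, columns=cols)
    out = out_anom + clim
    if "P" in out.columns:
        out["P"] = np.expm1(out["P"]).clip(lower=0.0)
    # never alter an observed cell
    out[~missing] = raw[~missing]
    result = series.copy()
    result[cols] = out
    if {"TX", "TM"} <= set(result.columns):
        swap = result["TM"] > result["TX"]
        if swap.any():
            tm = result.loc[swap, "TM"].copy()
            result.loc[swap, "TM"] = result.loc[swap, "TX"]
            result.loc[swap, "TX"] = tm
    mask = pd.DataFrame(False, index=series.index, columns=series.columns)
    mask[cols] = missing
    return result, mask


def impute_forest_rh_sr(target: pd.Series, predictors: pd.DataFrame,
                        ntree: int = 800, mtry: int = 2, seed: int = 0,
                        clip_range: tuple | None = None,
                        ) -> tuple[pd.Series, pd.Series]:
    """Fill gaps in an RH or SR series with a regression forest.

    The forest is trained on days where the target is observed, using the
    supplied predictor columns (typically TM, TX, P); predictions fill the
    gaps.  ``clip_range`` bounds the fill (RH to [0, 100]; SR floored at a
    small positive value) and defaults by the series name.  Gap days with a
    missing predictor are left missing and reported in the returned mask's
    attrs.  Returns (filled series, imputed mask).
    """
    if clip_range is None:
        name = (target.name or "").upper()
        clip_range = (0.0, 100.0) if name == "RH" else (1.0, None)
    missing = target.isna()
    if not missing.any():
        return target.copy(), pd.Series(False, index=target.index)
    pred_ok = predictors.notna().all(axis=1)
    train = (~missing) & pred_ok
    if int(train.sum()) < MIN_FOREST_DAYS:
        raise ValueError(
            f"only {int(train.sum())} training days; need >= {MIN_FOREST_DAYS}")
    rf = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                               random_state=seed, n_jobs=1)
    rf.fit(predictors[train].to_numpy(), target[train].to_numpy())
    fillable = missing & pred_ok
    out = target.copy()
    if fillable.any():
        yhat = rf.predict(predictors[fillable].to_numpy())
        lo, hi = clip_range
        if lo is not None:
            yhat = np.maximum(yhat, lo)
        if hi is not None:
            yhat = np.minimum(yhat, hi)
        out[fillable] = yhat
    mask = fillable.copy()
    mask.attrs["unfilled_days"] = int((missing & ~pred_ok).sum())
    return out, mask
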