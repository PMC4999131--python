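"""Conditional-inference regression forests.

Each tree is grown on a bootstrap sample.  At a node, ``mtry`` candidate
predictors are drawn without replacement and the split *variable* is chosen
by an association test, not by impurity gain: for a continuous candidate the
standardized linear statistic between the predictor and the response (its
permutation-null z-score), for a categorical candidate the maximum such
statistic over its level indicators.  The node is not split when the
Bonferroni-adjusted minimum p-value exceeds ``alpha_split`` or the node is
smaller than ``minsplit`` — an internal stopping rule that replaces pruning.
The split *point* then maximizes the standardized two-sample statistic
subject to ``minbucket`` observations per child.  Leaves predict the mean of
their training responses; the forest prediction is the mean over trees.

This separation of variable and cutpoint selection removes the bias of
impurity-based forests toward predictors with many distinct values, which is
what makes the permutation importances computed on top of it trustworthy for
explanation (see :mod:`riceclim.importance`).

The heavy loops (tree growth, prediction, permutation importance) are
numba-compiled; everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

MAX_CAT_LEVELS = 32


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters (explanation-oriented defaults)."""

    ntree: int = 2000
    mtry: int | None = None      # default: round(p/3)
    alpha_split: float = 0.05
    minsplit: int = 20
    minbucket: int = 7
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else int(round(p / 3))
        m = max(1, min(m, p))
        return m


@njit(cache=True)
def _two_sided_p(z):
    return math.erfc(abs(z) / math.sqrt(2.0))


@njit(cache=True)
def _predict_node(feat, thr, cmask, left, right, is_cat, row, override_j, override_v):
    node = 0
    while feat[node] >= 0:
        f = feat[node]
        x = override_v if f == override_j else row[f]
        if is_cat[f]:
            code = int(x)
            go_left = (cmask[node] >> code) & np.int64(1)
            node = left[node] if go_left else right[node]
        else:
            node = left[node] if x <= thr[node] else right[node]
    return node


@njit(cache=True)
def _grow_forest(X, y, is_cat, n_levels, ntree, mtry, alpha, minsplit,
                 minbucket, seed):
    n, p = X.shape
    max_leaves = n // max(minbucket, 1) + 2
    max_nodes = 2 * max_leaves + 1
    feat = np.full((ntree, max_nodes), -1, np.int64)
    thr = np.full((ntree, max_nodes), np.nan)
    cmask = np.zeros((ntree, max_nodes), np.int64)
    left = np.full((ntree, max_nodes), -1, np.int64)
    right = np.full((ntree, max_nodes), -1, np.int64)
    val = np.zeros((ntree, max_nodes))
    nnodes = np.zeros(ntree, np.int64)
    inbag = np.zeros((ntree, n), np.bool_)

    idx = np.empty(n, np.int64)
    tmp = np.empty(n, np.int64)
    stack_node = np.empty(max_nodes + 2, np.int64)
    stack_lo = np.empty(max_nodes + 2, np.int64)
    stack_hi = np.empty(max_nodes + 2, np.int64)
    perm = np.empty(p, np.int64)
    lvl_sum = np.empty(64, np.float64)
    lvl_cnt = np.empty(64, np.int64)
    lvl_mean = np.empty(64, np.float64)
    lvl_order = np.empty(64, np.int64)

    np.random.seed(seed)
    for t in range(ntree):
        for i in range(n):
            b = np.random.randint(0, n)
            idx[i] = b
            inbag[t, b] = True
        n_nodes = 1
        sp = 0
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        while sp >= 0:
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            sp -= 1
            m = hi - lo
            ysum = 0.0
            for i in range(lo, hi):
                ysum += y[idx[i]]
            ybar = ysum / m
            val[t, node] = ybar
            if m < minsplit or m < 2 * minbucket:
                continue
            yss = 0.0
            for i in range(lo, hi):
                d = y[idx[i]] - ybar
                yss += d * d
            if yss <= 0.0:
                continue
            yvar = yss / m  # population variance within the node

            # --- variable selection: smallest association-test p-value ---
            for j in range(p):
                perm[j] = j
            n_cand = mtry if mtry < p else p
            for j in range(n_cand):
                r = j + np.random.randint(0, p - j)
                tpm = perm[j]
                perm[j] = perm[r]
                perm[r] = tpm
            best_p = 2.0
            best_j = -1
            n_valid = 0
            for cidx in range(n_cand):
                j = perm[cidx]
                if is_cat[j]:
                    L = n_levels[j]
                    for l in range(L):
                        lvl_sum[l] = 0.0
                        lvl_cnt[l] = 0
                    for i in range(lo, hi):
                        code = int(X[idx[i], j])
                        lvl_sum[code] += y[idx[i]]
                        lvl_cnt[code] += 1
                    present = 0
                    maxz = 0.0
                    for l in range(L):
                        cl = lvl_cnt[l]
                        if cl == 0 or cl == m:
                            continue
                        present += 1
                        # indicator statistic: sum of y over the level vs null
                        mean_t = cl * ybar
                        var_t = cl * (m - cl) / (m - 1.0) * yvar
                        if var_t > 0:
                            z = abs(lvl_sum[l] - mean_t) / math.sqrt(var_t)
                            if z > maxz:
                                maxz = z
                    if present < 1:
                        continue
                    pval = _two_sided_p(maxz) * present
                    if pval > 1.0:
                        pval = 1.0
                else:
                    xsum = 0.0
                    for i in range(lo, hi):
                        xsum += X[idx[i], j]
                    xbar = xsum / m
                    sxy = 0.0
                    sxx = 0.0
                    for i in range(lo, hi):
                        dx = X[idx[i], j] - xbar
                        sxy += dx * (y[idx[i]] - ybar)
                        sxx += dx * dx
                    if sxx <= 0.0:
                        continue
                    z = sxy / math.sqrt(sxx * yss / (m - 1.0))
                    pval = _two_sided_p(z)
                n_valid += 1
                if pval < best_p:
                    best_p = pval
                    best_j = j
            if best_j < 0:
                continue
            p_adj = best_p * n_valid
            if p_adj > alpha:
                continue

            # --- cutpoint: maximize the standardized two-sample statistic ---
            j = best_j
            split_ok = False
            threshold = 0.0
            mask = np.int64(0)
            if is_cat[j]:
                L = n_levels[j]
                for l in range(L):
                    lvl_sum[l] = 0.0
                    lvl_cnt[l] = 0
                for i in range(lo, hi):
                    code = int(X[idx[i], j])
                    lvl_sum[code] += y[idx[i]]
                    lvl_cnt[code] += 1
                npres = 0
                for l in range(L):
                    if lvl_cnt[l] > 0:
                        lvl_mean[npres] = lvl_sum[l] / lvl_cnt[l]
                        lvl_order[npres] = l
                        npres += 1
                # order present levels by mean response, then scan as ordinal
                for a in range(1, npres):
                    mv = lvl_mean[a]
                    ov = lvl_order[a]
                    b2 = a - 1
                    while b2 >= 0 and lvl_mean[b2] > mv:
                        lvl_mean[b2 + 1] = lvl_mean[b2]
                        lvl_order[b2 + 1] = lvl_order[b2]
                        b2 -= 1
                    lvl_mean[b2 + 1] = mv
                    lvl_order[b2 + 1] = ov
                best_score = -1.0
                cum_s = 0.0
                cum_n = 0
                cut_at = -1
                for a in range(npres - 1):
                    l = lvl_order[a]
                    cum_s += lvl_sum[l]
                    cum_n += lvl_cnt[l]
                    if cum_n < minbucket or m - cum_n < minbucket:
                        continue
                    score = abs(cum_s - cum_n * ybar) / math.sqrt(
                        cum_n * float(m - cum_n))
                    if score > best_score:
                        best_score = score
                        cut_at = a
                if cut_at >= 0:
                    for a in range(cut_at + 1):
                        mask |= np.int64(1) << lvl_order[a]
                    split_ok = True
            else:
                xv = np.empty(m)
                yv = np.empty(m)
                for i in range(m):
                    xv[i] = X[idx[lo + i], j]
                order = np.argsort(xv)
                for i in range(m):
                    yv[i] = y[idx[lo + order[i]]]
                xs = xv[order]
                best_score = -1.0
                cum = 0.0
                cut_at = -1
                for i in range(m - 1):
                    cum += yv[i]
                    nl = i + 1
                    if nl < minbucket or m - nl < minbucket:
                        continue
                    if xs[i + 1] <= xs[i]:
                        continue
                    score = abs(cum - nl * ybar) / math.sqrt(nl * float(m - nl))
                    if score > best_score:
                        best_score = score
                        cut_at = i
                if cut_at >= 0:
                    threshold = 0.5 * (xs[cut_at] + xs[cut_at + 1])
                    split_ok = True
            if not split_ok:
                continue

            # --- partition the index segment (stable) ---
            nl = 0
            for i in range(lo, hi):
                xij = X[idx[i], j]
                if is_cat[j]:
                    go_left = (mask >> int(xij)) & np.int64(1)
                else:
                    go_left = xij <= threshold
                if go_left:
                    idx[lo + nl] = idx[i]
                    nl += 1
                else:
                    tmp[i - lo - nl] = idx[i]
            for i in range(m - nl):
                idx[lo + nl + i] = tmp[i]
            if nl == 0 or nl == m:
                continue
            feat[t, node] = j
            thr[t, node] = threshold
            cmask[t, node] = mask
            lc = n_nodes
            rc = n_nodes + 1
            n_nodes += 2
            left[t, node] = lc
            right[t, node] = rc
            sp += 1
            stack_node[sp] = lc
            stack_lo[sp] = lo
            stack_hi[sp] = lo + nl
            sp += 1
            stack_node[sp] = rc
            stack_lo[sp] = lo + nl
            stack_hi[sp] = hi
        nnodes[t] = n_nodes
    return feat, thr, cmask, left, right, val, nnodes, inbag


@njit(cache=True)
def _forest_predict(feat, thr, cmask, left, right, val, is_cat, X):
    ntree = feat.shape[0]
    n = X.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for t in range(ntree):
            node = _predict_node(feat[t], thr[t], cmask[t], left[t], right[t],
                                 is_cat, X[i], -1, 0.0)
            s += val[t, node]
        out[i] = s / ntree
    return out


@njit(cache=True)
def _oob_predictions(feat, thr, cmask, left, right, val, is_cat, X, inbag):
    ntree = feat.shape[0]
    n = X.shape[0]
    s = np.zeros(n)
    c = np.zeros(n, np.int64)
    for t in range(ntree):
        for i in range(n):
            if inbag[t, i]:
                continue
            node = _predict_node(feat[t], thr[t], cmask[t], left[t], right[t],
                                 is_cat, X[i], -1, 0.0)
            s[i] += val[t, node]
            c[i] += 1
    return s, c


@njit(cache=True)
def _permutation_vi(feat, thr, cmask, left, right, val, nnodes, is_cat,
                    X, y, inbag, cond, seed):
    """Per-predictor mean (over trees) increase of OOB MSE after permuting it.

    ``cond[j, k]`` marks covariate k as a conditioning variable for predictor
    j: the permutation of j is then restricted to the cells of the partition
    that the tree's own split points on those covariates induce (strata keyed
    by a hash of the per-covariate bins; collisions only merge strata and are
    astronomically rare).
    """
    ntree, max_nodes = feat.shape
    n, p = X.shape
    vi = np.zeros(p)
    used = np.zeros(p, np.int64)
    np.random.seed(seed)
    oob_idx = np.empty(n, np.int64)
    ths = np.empty(max_nodes, np.float64)
    for t in range(ntree):
        m = 0
        for i in range(n):
            if not inbag[t, i]:
                oob_idx[m] = i
                m += 1
        if m < 2:
            continue
        base_err = 0.0
        for ii in range(m):
            i = oob_idx[ii]
            node = _predict_node(feat[t], thr[t], cmask[t], left[t], right[t],
                                 is_cat, X[i], -1, 0.0)
            d = y[i] - val[t, node]
            base_err += d * d
        base_mse = base_err / m
        keys = np.empty(m, np.int64)
        permuted = np.empty(m)
        for j in range(p):
            for ii in range(m):
                keys[ii] = 0
            for k in range(p):
                if k == j or not cond[j, k] or is_cat[k]:
                    continue
                nth = 0
                for node in range(nnodes[t]):
                    if feat[t, node] == k:
                        ths[nth] = thr[t, node]
                        nth += 1
                if nth == 0:
                    continue
                for ii in range(m):
                    xv = X[oob_idx[ii], k]
                    b = 0
                    for q in range(nth):
                        if xv > ths[q]:
                            b += 1
                    keys[ii] = keys[ii] * np.int64(1315423911) + b
            order = np.argsort(keys)
            start = 0
            while start < m:
                end = start + 1
                while end < m and keys[order[end]] == keys[order[start]]:
                    end += 1
                g = end - start
                for a in range(g):
                    permuted[a] = X[oob_idx[order[start + a]], j]
                for a in range(g - 1, 0, -1):
                    b2 = np.random.randint(0, a + 1)
                    tv = permuted[a]
                    permuted[a] = permuted[b2]
                    permuted[b2] = tv
                for a in range(g):
                    i = oob_idx[order[start + a]]
                    node = _predict_node(feat[t], thr[t], cmask[t], left[t],
                                         right[t], is_cat, X[i], j,
                                         permuted[a])
                    d = y[i] - val[t, node]
                    vi[j] += d * d / m
                start = end
            vi[j] -= base_mse
            used[j] += 1
    for j in range(p):
        if used[j] > 0:
            vi[j] /= used[j]
    return vi


@njit(cache=True)
def _partial_profile(feat, thr, cmask, left, right, val, is_cat, X, j, grid):
    ntree = feat.shape[0]
    n = X.shape[0]
    out = np.zeros(len(grid))
    for g in range(len(grid)):
        s = 0.0
        for i in range(n):
            for t in range(ntree):
                node = _predict_node(feat[t], thr[t], cmask[t], left[t],
                                     right[t], is_cat, X[i], j, grid[g])
                s += val[t, node]
        out[g] = s / (n * ntree)
    return out


class ForestModel:
    """A fitted conditional-inference regression forest."""

    def __init__(self, arrays, is_cat, n_levels, feature_names, categories,
                 config: ForestConfig, n_samples: int):
        (self._feat, self._thr, self._cmask, self._left, self._right,
         self._val, self._nnodes, self.inbag) = arrays
        self.is_cat = is_cat
        self.n_levels = n_levels
        self.feature_names = list(feature_names)
        self.categories = categories  # per categorical feature: level labels
        self.config = config
        self.n_samples = n_samples

    @property
    def ntree(self) -> int:
        return self._feat.shape[0]

    def root_split_features(self) -> np.ndarray:
        return self._feat[:, 0].copy()

    def predict(self, X) -> np.ndarray:
        Xm = encode_matrix(X, self.feature_names, self.categories)
        return _forest_predict(self._feat, self._thr, self._cmask, self._left,
                               self._right, self._val, self.is_cat, Xm)

    def _tree_arrays(self):
        return (self._feat, self._thr, self._cmask, self._left, self._right,
                self._val, self._nnodes)


def encode_matrix(X, feature_names=None, categories: dict | None = None):
    """Coerce a DataFrame (or array) to the float matrix the kernels expect.

    Categorical/object columns become integer level codes stored as floats.
    When ``categories`` is given (from a fitted model), unseen levels raise.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            X = X[feature_names]
        cols = []
        for c in X.columns:
            col = X[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                if categories and c in categories:
                    cat = pd.Categorical(col, categories=categories[c])
                    if cat.isna().any() and not col.isna().any():
                        raise ValueError(f"unseen level in column {c!r}")
                    codes = cat.codes
                else:
                    codes = pd.Categorical(col).codes
                cols.append(codes.astype(np.float64))
            else:
                cols.append(col.to_numpy(dtype=np.float64))
        return np.ascontiguousarray(np.column_stack(cols))
    return np.ascontiguousarray(np.asarray(X, dtype=np.float64))


def _encode_training(X: pd.DataFrame | np.ndarray):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        is_cat = np.zeros(len(names), np.bool_)
        n_levels = np.zeros(len(names), np.int64)
        categories: dict = {}
        for i, c in enumerate(names):
            col = X[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                cat = pd.Categorical(col)
                if len(cat.categories) > MAX_CAT_LEVELS:
                    raise ValueError(
                        f"categorical predictor {c!r} has "
                        f"{len(cat.categories)} levels (> {MAX_CAT_LEVELS})")
                is_cat[i] = True
                n_levels[i] = len(cat.categories)
                categories[c] = list(cat.categories)
        Xm = encode_matrix(X, names, categories)
        return Xm, names, is_cat, n_levels, categories
    Xm = encode_matrix(X)
    p = Xm.shape[1]
    return (Xm, [f"x{i}" for i in range(p)], np.zeros(p, np.bool_),
            np.zeros(p, np.int64), {})


def fit_cif(X, y, config: ForestConfig | None = None) -> ForestModel:
    """Fit a conditional-inference forest regressing ``y`` on ``X``."""
    config = config or ForestConfig()
    Xm, names, is_cat, n_levels, categories = _encode_training(X)
    yv = np.ascontiguousarray(np.asarray(y, dtype=np.float64))
    n, p = Xm.shape
    if len(yv) != n:
        raise ValueError("X and y lengths differ")
    if np.isnan(Xm).any() or np.isnan(yv).any():
        raise ValueError("missing values are not allowed at fit time")
    if np.var(yv) == 0:
        raise ValueError("constant response")
    mtry = config.resolve_mtry(p)
    arrays = _grow_forest(Xm, yv, is_cat, n_levels, int(config.ntree), mtry,
                          float(config.alpha_split), int(config.minsplit),
                          int(config.minbucket), int(config.seed) % (2 ** 31))
    model = ForestModel(arrays, is_cat, n_levels, names, categories, config, n)
    model._Xm = Xm  # training design retained for OOB scoring / importance
    model._y = yv
    return model


def insample_r2(model: ForestModel) -> float:
    """Training R-squared of the fitted forest.

    Because split selection stops on association-test significance, these
    forests barely overfit and the training R-squared tracks the population
    signal closely (near zero on pure-noise responses); it is therefore a
    stable non-negative performance weight for importance scaling, where the
    out-of-bag variant's negative excursions on null data would degenerate.
    """
    yhat = _forest_predict(*model._tree_arrays()[:6], model.is_cat, model._Xm)
    y = model._y
    return float(1.0 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2))


def oob_r2(model: ForestModel, X=None, y=None) -> float:
    """Out-of-bag R-squared; may be negative and is deliberately not clipped."""
    Xm = model._Xm if X is None else encode_matrix(X, model.feature_names,
                                                   model.categories)
    yv = model._y if y is None else np.asarray(y, dtype=np.float64)
    if np.var(yv) == 0:
        raise ValueError("zero variance in y")
    s, c = _oob_predictions(*model._tree_arrays()[:6], model.is_cat, Xm,
                            model.inbag)
    ok = c > 0
    yhat = s[ok] / c[ok]
    resid = np.sum((yv[ok] - yhat) ** 2)
    total = np.sum((yv[ok] - yv[ok].mean()) ** 2)
    return float(1.0 - resid / total)
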