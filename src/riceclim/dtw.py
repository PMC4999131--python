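"""Dynamic time warping distances between cropping-event weather patterns.

Events are compared through their whole daily series (TX, TM, P, RH, SR over
the ~126-day cycle) rather than through summary statistics, so short heat or
drought spells still separate events.  The distance between two events is the
sum over the five variables of the univariate DTW distances between pooled
z-scored series ("independent" multivariate DTW, equal weights); a
"dependent" variant using the Euclidean day-vector cost is available for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass
class EventSeriesBundle:
    """One event's daily weather series; lengths may differ across events."""

    event_id: str
    series: dict[str, np.ndarray]
    yield_kg_ha: float = np.nan
    cultivar: str = ""

    def __post_init__(self):
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) > 1:
            raise ValueError("all variables of one event must share a length")


@njit(cache=True)
def _dtw_cost(a, b):
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = np.inf
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        for j in range(m + 1):
            prev[j] = cur[j]
    return prev[m]


@njit(cache=True)
def _dtw_cost_multi(A, B):
    # dependent DTW: local cost = Euclidean norm over the variable axis
    n, m, d = A.shape[0], B.shape[0], A.shape[1]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = np.inf
        for j in range(1, m + 1):
            c = 0.0
            for k in range(d):
                diff = A[i - 1, k] - B[j - 1, k]
                c += diff * diff
            c = np.sqrt(c)
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        for j in range(m + 1):
            prev[j] = cur[j]
    return prev[m]


def dtw_distance(a, b) -> float:
    """Classic DTW cost: |a_i - b_j| local cost, symmetric steps
    (match/insert/delete), boundary-anchored, no window constraint."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series must be finite")
    return float(_dtw_cost(a, b))


def standardize_event_series(bundles: list[EventSeriesBundle],
                             ) -> list[EventSeriesBundle]:
    """Pooled z-scoring per climatic variable over all days of all events.

    A variable with zero pooled variance carries no contrast and is dropped
    with a warning.  Idempotent (re-standardizing changes nothing).
    """
    if len(bundles) < 2:
        raise ValueError("need at least two events to standardize")
    variables = list(bundles[0].series)
    for bnd in bundles:
        if list(bnd.series) != variables:
            raise ValueError("all bundles must share the same variable set")
    out_series: list[dict[str, np.ndarray]] = [{} for _ in bundles]
    for var in variables:
        pooled = np.concatenate([b.series[var] for b in bundles])
        mu, sd = pooled.mean(), pooled.std()
        if sd == 0:
            warnings.warn(f"variable {var!r} constant across events; dropped",
                          stacklevel=2)
            continue
        for i, bnd in enumerate(bundles):
            out_series[i][var] = (bnd.series[var] - mu) / sd
    return [EventSeriesBundle(b.event_id, s, b.yield_kg_ha, b.cultivar)
            for b, s in zip(bundles, out_series)]


def event_distance(a: EventSeriesBundle, b: EventSeriesBundle,
                   weights: dict[str, float] | None = None,
                   mode: str = "independent") -> float:
    """Distance between two (standardized) events.

    ``independent``: weighted sum of per-variable DTW distances (default,
    equal weights).  ``dependent``: single DTW over the per-day vectors with
    Euclidean local cost.
    """
    if set(a.series) != set(b.series):
        raise ValueError("events have different variable sets")
    if mode == "independent":
        total = 0.0
        for var in a.series:
            w = 1.0 if weights is None else weights.get(var, 1.0)
            total += w * dtw_distance(a.series[var], b.series[var])
        return total
    if mode == "dependent":
        variables = sorted(a.series)
        A = np.column_stack([a.series[v] for v in variables])
        B = np.column_stack([b.series[v] for v in variables])
        return float(_dtw_cost_multi(np.ascontiguousarray(A),
                                     np.ascontiguousarray(B)))
    raise ValueError(f"unknown mode {mode!r}")


def pairwise_distance_matrix(bundles: list[EventSeriesBundle],
                             weights: dict[str, float] | None = None,
                             mode: str = "independent") -> np.ndarray:
    """Symmetric zero-diagonal matrix of event distances (unordered pairs
    computed once and mirrored)."""
    n = len(bundles)
    if n < 2:
        raise ValueError("need at least two events")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = event_distance(bundles[i], bundles[j],
                                               weights=weights, mode=mode)
    return d
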