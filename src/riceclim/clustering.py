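"""Hierarchical clustering of cropping events and per-cluster yield analysis.

Agglomeration runs on a precomputed (DTW) distance matrix with
Lance-Williams updates.  The default "ward" linkage updates *squared*
distances, so merge heights read as within-cluster inertia increases and
the elbow on successive heights selects the cluster count.  Average and
complete linkage are available as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .letters import LetterGrouping, kw_letter_grouping


def hierarchical_cluster(dmat: np.ndarray, linkage: str = "ward") -> np.ndarray:
    """Agglomerative clustering on a precomputed distance matrix.

    Returns a linkage matrix in the conventional (n-1, 4) layout: the two
    merged cluster ids (original points are 0..n-1, merges continue upward),
    the merge height, and the new cluster's size.  Ward heights live on the
    squared-distance (inertia) scale.
    """
    d = np.asarray(dmat, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    work = d ** 2 if linkage == "ward" else d.copy()
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    ids = {i: i for i in range(n)}
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = work[i, j]

    def get(a, b):
        return D[(a, b) if a < b else (b, a)]

    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        bd = np.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                v = get(a, b)
                if v < bd:
                    bd = v
                    best = (a, b)
        a, b = best
        na, nb = sizes[a], sizes[b]
        Z[step] = (min(ids[a], ids[b]), max(ids[a], ids[b]), bd, na + nb)
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac, dbc = get(a, c), get(b, c)
            if linkage == "ward":
                v = ((na + nc) * dac + (nb + nc) * dbc - nc * bd) / (na + nb + nc)
            elif linkage == "average":
                v = (na * dac + nb * dbc) / (na + nb)
            else:
                v = max(dac, dbc)
            key = (a, c) if a < c else (c, a)
            D[key] = v
        active.remove(b)
        sizes[a] = na + nb
        ids[a] = next_id
        next_id += 1
    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels 1..k obtained by undoing the last k-1 merges."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError("k outside [1, n]")
    parent = {}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        members[n + step] = members.pop(a) + members.pop(b)
    labels = np.zeros(n, dtype=int)
    for lab, (_, mem) in enumerate(sorted(members.items()), start=1):
        labels[mem] = lab
    return labels


def select_k_inertia_gain(Z: np.ndarray, k_min: int = 2,
                          k_max: int = 20) -> int:
    """Elbow on the dendrogram heights.

    Let H(k) be the height of the merge that collapses the k-cluster
    solution into k-1 clusters (the cost of giving up k clusters).  The
    chosen k maximizes H(k)/H(k+1) over [k_min, k_max]: a good k is one
    whose own structure is cheap to build but expensive to destroy.  Ties
    pick the smallest k; a flat dendrogram returns k_min with a warning.
    """
    n = Z.shape[0] + 1
    if k_max >= n:
        k_max = n - 1
    if k_min < 2 or k_min > k_max:
        raise ValueError("need 2 <= k_min <= k_max < n")
    heights = Z[:, 2]
    if np.allclose(heights, heights[0]):
        warnings.warn("flat dendrogram; returning k_min", stacklevel=2)
        return k_min

    def H(k):  # merge reducing k clusters to k-1 is merge number n-k+1
        return heights[n - k]

    best_k, best_ratio = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        denom = H(k + 1)
        num = H(k)
        ratio = np.inf if denom == 0 and num > 0 else (
            -np.inf if denom == 0 else num / denom)
        if ratio > best_ratio + 1e-12:
            best_ratio = ratio
            best_k = k
    return best_k


@dataclass
class ClusterYieldSummary:
    table: pd.DataFrame               # per-cluster n / mean / median / sd
    letters: LetterGrouping | None    # across clusters (size>1 clusters only)
    singletons: list[int] = field(default_factory=list)


def cluster_yield_analysis(labels: np.ndarray, yields: np.ndarray,
                           alpha: float = 0.05) -> ClusterYieldSummary:
    """Per-cluster yield statistics plus letter groups across clusters.

    Clusters are reported in decreasing order of median yield; size-1
    clusters appear in the summary but are excluded from the rank test.
    """
    labels = np.asarray(labels)
    yields = np.asarray(yields, dtype=float)
    if len(labels) != len(yields):
        raise ValueError("labels and yields must align")
    rows = []
    samples = {}
    singles = []
    for c in np.unique(labels):
        vals = yields[labels == c]
        rows.append({"cluster": int(c), "n": len(vals),
                     "mean": float(vals.mean()),
                     "median": float(np.median(vals)),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan})
        if len(vals) > 1:
            samples[str(int(c))] = vals
        else:
            singles.append(int(c))
    table = (pd.DataFrame(rows).sort_values("median", ascending=False)
             .reset_index(drop=True))
    letters = kw_letter_grouping(samples, alpha=alpha) if len(samples) >= 2 else None
    return ClusterYieldSummary(table, letters, singles)


def cultivar_within_cluster(labels: np.ndarray, yields: np.ndarray,
                            cultivars: np.ndarray, min_cluster_n: int = 10,
                            min_cultivar_n: int = 5, alpha: float = 0.05,
                            ) -> dict[int, LetterGrouping | str]:
    """Cultivar yield comparison inside each sufficiently large cluster.

    Clusters with fewer than ``min_cluster_n`` events are skipped entirely;
    within a cluster, cultivars with fewer than ``min_cultivar_n``
    observations are pooled out of the test.  A cluster with fewer than two
    eligible cultivars is reported as "no comparison possible".
    """
    labels = np.asarray(labels)
    yields = np.asarray(yields, dtype=float)
    cultivars = np.asarray(cultivars)
    if not (len(labels) == len(yields) == len(cultivars)):
        raise ValueError("inputs must align")
    out: dict[int, LetterGrouping | str] = {}
    for c in np.unique(labels):
        m = labels == c
        if int(m.sum()) < min_cluster_n:
            continue
        samples = {}
        for cv in np.unique(cultivars[m]):
            vals = yields[m & (cultivars == cv)]
            if len(vals) >= min_cultivar_n:
                samples[str(cv)] = vals
        if len(samples) < 2:
            out[int(c)] = "no comparison possible"
        else:
            out[int(c)] = kw_letter_grouping(samples, alpha=alpha)
    return out
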