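"""Kruskal-Wallis multiple comparison with compact letter display.

Groups sharing a letter do not differ significantly at the stated level.
The omnibus test is the Kruskal-Wallis H on pooled midranks; pairwise
comparisons use the mean-rank difference with its normal-approximation null
standard error (Dunn's criterion, tie-corrected), by default without
multiplicity correction — the 5%-level per-comparison convention common in
agronomic reporting — with a Bonferroni option.  Letters are assigned by the
insert-and-absorb sweep over items sorted by decreasing mean rank: a letter
covers a maximal run of items that are all mutually non-significant, so a
shared letter always certifies a non-significant difference.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LetterGrouping:
    letters: dict[str, str]          # item -> letter string, e.g. "ab"
    p_values: pd.DataFrame           # symmetric pairwise p-value matrix
    mean_ranks: pd.Series
    alpha: float
    kw_statistic: float
    kw_p_value: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _letter_symbols(k: int) -> list[str]:
    base = string.ascii_lowercase
    out = list(base)
    while len(out) < k:
        out += [a + b for a in base for b in base]
    return out[:k]


def pairwise_rank_pvalues(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn-style pairwise p-values from pooled midranks (tie corrected)."""
    items = list(samples)
    sizes = {i: len(samples[i]) for i in items}
    pooled = np.concatenate([np.asarray(samples[i], float) for i in items])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for i in items:
        mean_ranks[i] = ranks[pos:pos + sizes[i]].mean()
        pos += sizes[i]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pmat = pd.DataFrame(np.ones((len(items), len(items))), index=items,
                        columns=items)
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            ia, ib = items[a], items[b]
            se = np.sqrt(base_var * (1.0 / sizes[ia] + 1.0 / sizes[ib]))
            if se == 0:
                p = 1.0
            else:
                z = abs(mean_ranks[ia] - mean_ranks[ib]) / se
                p = float(stats.norm.sf(z) * 2)
            pmat.loc[ia, ib] = pmat.loc[ib, ia] = p
    return pmat, pd.Series(mean_ranks)


def kw_letter_grouping(samples: dict[str, np.ndarray], alpha: float = 0.05,
                       p_adjust: str | None = None) -> LetterGrouping:
    """Letter groups over the items' value distributions.

    ``p_adjust="bonferroni"`` multiplies pairwise p-values by the number of
    comparisons before thresholding.
    """
    items = list(samples)
    if len(items) < 2:
        raise ValueError("need at least two items")
    for i in items:
        if len(samples[i]) < 2:
            raise ValueError(f"item {i!r} has fewer than 2 values")
    arrays = [np.asarray(samples[i], float) for i in items]
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical: a single letter covers everything
        letters = {i: "a" for i in items}
        pmat = pd.DataFrame(np.ones((len(items), len(items))), index=items,
                            columns=items)
        mr = pd.Series({i: (len(np.concatenate(arrays)) + 1) / 2 for i in items})
        return LetterGrouping(letters, pmat, mr, alpha, 0.0, 1.0)
    kw_stat, kw_p = stats.kruskal(*arrays)
    pmat, mean_ranks = pairwise_rank_pvalues(samples)
    padj = pmat.copy()
    if p_adjust == "bonferroni":
        m = len(items) * (len(items) - 1) / 2
        padj = (pmat * m).clip(upper=1.0)
    elif p_adjust is not None:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    order = list(mean_ranks.sort_values(ascending=False).index)
    different = padj < alpha

    def run_ok(lo: int, hi: int) -> bool:
        for a in range(lo, hi + 1):
            for b in range(a + 1, hi + 1):
                if different.loc[order[a], order[b]]:
                    return False
        return True

    # maximal mutually non-significant runs over the sorted order
    runs: list[tuple[int, int]] = []
    for lo in range(len(order)):
        hi = lo
        while hi + 1 < len(order) and run_ok(lo, hi + 1):
            hi += 1
        runs.append((lo, hi))
    # absorb runs contained in an earlier, wider run
    kept: list[tuple[int, int]] = []
    for r in runs:
        if not any(k[0] <= r[0] and r[1] <= k[1] for k in kept):
            kept.append(r)
    symbols = _letter_symbols(len(kept))
    letters = {i: "" for i in items}
    for sym, (lo, hi) in zip(symbols, kept):
        for a in range(lo, hi + 1):
            letters[order[a]] += sym
    return LetterGrouping(letters, pmat, mean_ranks, alpha,
                          float(kw_stat), float(kw_p))
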