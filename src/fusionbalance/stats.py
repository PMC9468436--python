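"""Shared statistical helpers: reporting-grade rounding, binomial CIs and a
Monte-Carlo Fisher exact test for tables larger than 2x2.

Rounding here is *half away from zero* (so 52.5 -> 53), the convention of
clinical frequency tables, rather than Python's banker's rounding.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "round_half_away",
    "percent",
    "mean_half_away",
    "clopper_pearson",
    "fisher_exact_mc",
]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (52.5 -> 53, -2.5 -> -3)."""
    d = Decimal(repr(float(x))).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP)
    return float(d)


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """``100 * count / total`` rounded half-away-from-zero.

    Computed in exact decimal arithmetic so printed-table ratios like
    21/40 reproduce 53 (not the 52 binary floats would give).
    """
    if total == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    d = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        _quantum(ndigits), rounding=ROUND_HALF_UP
    )
    return float(d)


def mean_half_away(values: Sequence[float], ndigits: int = 1) -> float:
    """Arithmetic mean rounded half-away-from-zero, in decimal arithmetic.

    Each value is taken at its decimal (repr) face value, so a mean of
    one-decimal medians such as 23.1/6 = 3.85 rounds up to 3.9.
    """
    vals = [Decimal(repr(float(v))) for v in values]
    if not vals:
        raise ValueError("mean of an empty sequence")
    d = (sum(vals) / len(vals)).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP)
    return float(d)


def clopper_pearson(count: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, as proportions."""
    if total <= 0:
        raise ValueError("total must be positive")
    lo, hi = proportion_confint(count, total, alpha=alpha, method="beta")
    return float(lo), float(hi)


def fisher_exact_mc(
    table: np.ndarray | Sequence[Sequence[int]],
    n_resamples: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo Fisher exact test for an r x c contingency table.

    Tables are resampled conditionally on both margins by permuting column
    labels against fixed row membership (the multivariate hypergeometric
    null); the p-value is the fraction of resamples whose conditional
    probability does not exceed the observed table's, with the standard
    +1 correction so p is never exactly 0.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    r, c = tab.shape
    row_tot = tab.sum(axis=1)
    col_tot = tab.sum(axis=0)
    n = int(tab.sum())
    if n == 0:
        raise ValueError("empty table")

    def neg_log_prob(cells: np.ndarray) -> np.ndarray:
        # conditional probability up to a margin-only constant
        return gammaln(cells + 1).sum(axis=(-2, -1))

    obs = neg_log_prob(tab)
    col_vec = np.repeat(np.arange(c, dtype=np.int8 if c < 127 else np.int64), col_tot)
    row_edges = np.concatenate([[0], np.cumsum(row_tot)])
    rng = np.random.default_rng(seed)

    hits = 0
    done = 0
    chunk = max(1, min(n_resamples, 20_000_000 // max(n, 1)))
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        perm = rng.permuted(np.broadcast_to(col_vec, (m, n)).copy(), axis=1)
        cells = np.empty((m, r, c), dtype=np.int64)
        for i in range(r):
            seg = perm[:, row_edges[i] : row_edges[i + 1]]
            for j in range(c):
                cells[:, i, j] = (seg == j).sum(axis=1)
        sim = neg_log_prob(cells)
        # larger sum of lgamma(cell+1) == smaller table probability
        hits += int((sim >= obs - 1e-9).sum())
        done += m
    return (hits + 1) / (n_resamples + 1)
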