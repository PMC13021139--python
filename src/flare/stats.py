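"""Self-contained nonparametric statistics used across the pipeline.

Exact two-sided Wilcoxon tests are computed by enumerating the null
distribution of the rank statistic (dynamic programming over rank sums,
equivalent to full enumeration of the 2^n sign assignments / C(N, n1)
group assignments); the normal approximation with tie and continuity
corrections is used beyond the exact regime.  Spearman's rho is the Pearson
correlation of mid-ranks, with a Fisher-z confidence interval using the
Fieller-adjusted standard error sqrt(1.06 / (n - 3)).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str              # "exact" | "normal_approx"
    n_used: int
    zeros_dropped: int = 0
    ties: int = 0


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@lru_cache(maxsize=64)
def _signed_rank_null_counts(n: int) -> tuple[int, ...]:
    """counts[w] = number of sign assignments with positive-rank sum w.

    Polynomial product over prod_{r=1..n} (1 + x^r); total mass 2^n.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=object)
    counts[0] = 1
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r].copy()
    return tuple(int(c) for c in counts)


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on (a, b) pairs.

    Zero differences are dropped (classical convention).  Exact p by null
    enumeration when n <= 25 and |differences| are tie-free; otherwise
    normal approximation with tie and continuity corrections.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b)")
    d = arr[:, 0] - arr[:, 1]
    zeros = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n < 2:
        raise ValueError("signed-rank test undefined: fewer than 2 nonzero "
                         "differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n_ties = n - len(np.unique(np.abs(d)))

    if n <= 25 and n_ties == 0:
        counts = _signed_rank_null_counts(n)
        total = 2 ** n
        w = int(round(w_pos))
        p_le = sum(counts[: w + 1]) / total
        p_ge = sum(counts[w:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(w_pos, p, "exact", n, zeros, 0)

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_pos - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(w_pos, p, "normal_approx", n, zeros, n_ties)


@lru_cache(maxsize=64)
def _rank_sum_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """counts[s] = number of n1-subsets of ranks {1..n1+n2} summing to s."""
    n = n1 + n2
    max_s = n1 * n + 1
    # dp[k][s]: subsets of size k with sum s
    dp = [np.zeros(max_s, dtype=object) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k][r:] = dp[k][r:] + dp[k - 1][:-r].copy()
    return tuple(int(c) for c in dp[n1])


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Statistic is the rank sum of ``x`` in the pooled mid-ranking.  Exact p
    by enumeration over group assignments when n1+n2 <= 20 and the pooled
    data are tie-free; otherwise normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    n_ties = len(pooled) - len(np.unique(pooled))

    if n1 + n2 <= 20 and n_ties == 0:
        counts = _rank_sum_null_counts(n1, n2)
        from math import comb
        total = comb(n1 + n2, n1)
        s = int(round(r1))
        p_le = sum(counts[: s + 1]) / total
        p_ge = sum(counts[s:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(r1, p, "exact", n1 + n2, 0, 0)

    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    diff = r1 - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(r1, p, "normal_approx", n, 0, n_ties)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho with a 95% Fisher-z (Fieller-adjusted) CI and a
    t-approximation p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need n >= 4 equal-length vectors")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if abs(rho) >= 1.0 - 1e-15:
        return CorrelationResult(rho, rho, rho, 0.0, n)

    z = np.arctanh(rho)
    se = np.sqrt(1.06 / (n - 3))
    zcrit = sps.norm.ppf(0.975)
    ci_low = float(np.tanh(z - zcrit * se))
    ci_high = float(np.tanh(z + zcrit * se))
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return CorrelationResult(rho, ci_low, ci_high, p, n)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional helper for report tables)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
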