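"""Exact small-sample Wilcoxon tests.

Per-family insertion counts are small integers, so ties are the norm and
large-sample approximations are unreliable.  Both tests therefore use the
exact conditional null distribution given the observed (mid)rank pattern,
computed by dynamic programming over doubled midranks (doubling makes tied
midranks integral).  For larger samples they fall back to the standard
normal approximation with continuity correction via scipy.

``signed_rank_test`` — paired Wilcoxon signed-rank; zero differences are
dropped.  ``rank_sum_test`` — two-sample Wilcoxon rank-sum (Mann-Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "signed_rank_test", "rank_sum_test"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    alternative: str
    direction: str  # sign of the observed effect: "greater", "less" or "none"
    method: str


def _direction(effect: float) -> str:
    return "greater" if effect > 0 else "less" if effect < 0 else "none"


def signed_rank_test(
    x,
    y=None,
    alternative: str = "two-sided",
    exact_max: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank test on differences ``x - y`` (or on ``x`` alone).

    Exact conditional p-value for up to ``exact_max`` informative (non-zero)
    pairs, normal approximation with continuity correction beyond.  The
    statistic is W+, the sum of midranks of positive differences.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, alternative, "none", "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    if n <= exact_max:
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = r2.sum()
        # counts of sign assignments by doubled W+; exact even with ties
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            dist[r:] += dist[:-r]
        w2 = int(round(2 * w_plus))
        denom = 2.0**n
        p_greater = dist[w2:].sum() / denom
        p_less = dist[: w2 + 1].sum() / denom
        method = "exact"
    else:
        res_g = sps.wilcoxon(d, alternative="greater", method="approx", correction=True)
        res_l = sps.wilcoxon(d, alternative="less", method="approx", correction=True)
        p_greater, p_less = float(res_g.pvalue), float(res_l.pvalue)
        method = "normal-approx"
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(w_plus, p, n, alternative, _direction(w_plus - mean_w), method)


def rank_sum_test(
    x,
    y,
    alternative: str = "two-sided",
    exact_max: int = 25,
) -> TestResult:
    """Wilcoxon rank-sum test; the statistic is the rank sum of ``x``.

    Exact conditional distribution (ties included) when both groups have at
    most ``exact_max`` observations, otherwise the normal approximation with
    continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_x = float(ranks[:nx].sum())
    mean_w = nx * (nx + ny + 1) / 2.0
    if nx <= exact_max and ny <= exact_max:
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        n = nx + ny
        # ways[j, s]: subsets of size j with doubled rank sum s
        ways = np.zeros((nx + 1, total + 1))
        ways[0, 0] = 1.0
        for r in r2:
            ways[1:, r:] += ways[:-1, :-r]
        denom = comb(n, nx)
        w2 = int(round(2 * w_x))
        p_greater = ways[nx, w2:].sum() / denom
        p_less = ways[nx, : w2 + 1].sum() / denom
        method = "exact"
    else:
        res_g = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        res_l = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        p_greater, p_less = float(res_g.pvalue), float(res_l.pvalue)
        method = "normal-approx"
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(w_x, p, nx + ny, alternative, _direction(w_x - mean_w), method)
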