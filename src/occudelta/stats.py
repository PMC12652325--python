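"""Rank statistics with explicit small-sample policies.

Two primitives are exposed:

* ``rank_sum_test`` — two-sided Wilcoxon rank-sum (Mann-Whitney). For both
  group sizes <= 8 the null distribution of the rank sum is enumerated
  exactly over all C(n+m, n) group assignments, with average ranks for ties
  (so tied data are handled exactly, unlike the classic no-tie tables).
  Larger groups use the normal approximation with tie correction and
  continuity correction.

* ``spearman_test`` — Spearman rank correlation with average-rank ties.
  Two-sided P uses the t-approximation for n > 25; below that the P value
  comes from a permutation null (full enumeration when n! is enumerable,
  n <= 9, otherwise a seeded Monte-Carlo permutation test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
from scipy import stats as sps

EXACT_RANKSUM_MAX = 8
SPEARMAN_T_MIN_N = 26  # t-approximation at n > 25
SPEARMAN_EXACT_MAX_N = 9  # 9! = 362880 permutations still enumerable
MC_PERMUTATIONS = 19999


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int = 0


def _rank_sum_statistic(pooled_ranks: np.ndarray, idx: Sequence[int]) -> float:
    return float(pooled_ranks[list(idx)].sum())


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Statistic: sum of (average) ranks of x in the pooled sample. Exact
    enumeration when len(x) <= 8 and len(y) <= 8; normal approximation with
    tie and continuity corrections otherwise. All-tied input returns P = 1
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    if np.all(pooled == pooled[0]):
        warnings.warn("rank-sum test on all-tied input; P = 1")
        return TestResult(statistic=w, pvalue=1.0, n1=n, n2=m)

    if n <= EXACT_RANKSUM_MAX and m <= EXACT_RANKSUM_MAX:
        mu = n * (n + m + 1) / 2.0
        obs_dev = abs(w - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n + m), n):
            total += 1
            if abs(_rank_sum_statistic(ranks, idx) - mu) >= obs_dev - 1e-12:
                extreme += 1
        return TestResult(statistic=w, pvalue=extreme / total, n1=n, n2=m)

    # normal approximation with tie correction and continuity correction
    mu = n * (n + m + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((nm) * (nm - 1))
    var = n * m / 12.0 * ((nm + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, pvalue=1.0, n1=n, n2=m)
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(statistic=w, pvalue=p, n1=n, n2=m)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(rho)


def spearman_test(x: Sequence[float], y: Sequence[float], seed: int = 0) -> TestResult:
    """Spearman rank correlation with a size-dependent two-sided P policy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("spearman_test requires n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("spearman_test requires non-constant inputs")
    rho = _spearman_rho(rx, ry)

    if n >= SPEARMAN_T_MIN_N:
        # matches scipy.stats.spearmanr's t-distribution approximation
        with np.errstate(divide="ignore"):
            t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = min(1.0, 2.0 * sps.t.sf(abs(t), n - 2))
        return TestResult(statistic=rho, pvalue=p, n1=n)

    obs = abs(rho)
    if n <= SPEARMAN_EXACT_MAX_N:
        total = 0
        extreme = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_spearman_rho(rx, ry[list(perm)])) >= obs - 1e-12:
                extreme += 1
        return TestResult(statistic=rho, pvalue=extreme / total, n1=n)

    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(MC_PERMUTATIONS):
        if abs(_spearman_rho(rx, rng.permutation(ry))) >= obs - 1e-12:
            extreme += 1
    # +1 correction keeps the Monte-Carlo P valid (never exactly 0)
    p = (extreme + 1) / (MC_PERMUTATIONS + 1)
    return TestResult(statistic=rho, pvalue=p, n1=n)
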