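"""Rank-sum and t statistics used for the boxplot and qPCR comparisons.

The Wilcoxon rank-sum test uses exact enumeration of all rank assignments
for small tie-free samples (n + m <= 12 by default) and a tie-corrected,
continuity-corrected normal approximation otherwise.  The t test is the
two-tailed unpaired Student test with pooled variance (Welch optional).
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .intervals import ValidationError

EXACT_LIMIT = 12


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of the (mid)ranks of ``x`` in the
    pooled sample.  Exact p-values enumerate all C(n+m, n) assignments of
    ranks to the first sample and are used when ``n + m <= exact_limit``
    and the pooled sample has no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(np.sum(ranks[:n]))
    has_ties = len(np.unique(pooled)) < n + m

    if n + m <= exact_limit and not has_ties:
        # enumerate every way the n ranks of x can fall among 1..n+m
        mu = n * (n + m + 1) / 2.0
        dev = abs(w - mu)
        hits = 0
        for combo in combinations(range(1, n + m + 1), n):
            if abs(sum(combo) - mu) >= dev - 1e-12:
                hits += 1
        return w, hits / comb(n + m, n)

    return w, _normal_approx_p(w, ranks, n, m)


def _normal_approx_p(w: float, ranks: np.ndarray, n: int, m: int) -> float:
    big_n = n + m
    mu = n * (big_n + 1) / 2.0
    # tie correction over groups of equal pooled values
    _, counts = np.unique(ranks, return_counts=True)
    # counts of tied *values*: a midrank shared by t observations appears t times
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return 1.0  # all observations identical
    diff = w - mu
    # continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def t_test_two_tailed(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> Tuple[float, float]:
    """Two-tailed unpaired t test (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t test requires >= 2 observations per sample")
    if not welch and np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValidationError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def stars(p: float, alphas: Tuple[float, float, float] = (0.05, 0.01, 0.001)) -> str:
    """Significance annotation: ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    a1, a2, a3 = alphas
    if p < a3:
        return "***"
    if p < a2:
        return "**"
    if p < a1:
        return "*"
    return "ns"
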