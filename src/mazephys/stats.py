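"""Shared nonparametric tests.

Thin wrappers around SciPy that pin down the conventions used
throughout the package: two-sided tests, exact enumeration for small
untied samples, tie-corrected normal approximation otherwise, and
explicit handling of the fully degenerate case (all observations
identical) where the asymptotic machinery divides by zero.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_p", "binomial_p", "spearman"]

_EXACT_MAX = 10  # exact Mann-Whitney enumeration up to this group size


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when both groups have at most 10
    observations and the pooled sample is tie-free; otherwise the
    normal approximation with tie correction and continuity correction.
    Returns 1.0 when every pooled value is identical.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if x.size <= _EXACT_MAX and y.size <= _EXACT_MAX and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def binomial_p(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of ``k`` successes in ``n`` trials."""
    if n < 1:
        raise ValueError("binomial test needs at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation and its p-value (ties mid-ranked)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
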