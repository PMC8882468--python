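"""Nonparametric two-sample location inference.

Mann-Whitney U test with a Hodges-Lehmann shift estimate and confidence
interval. The p-value comes from the exact U distribution when the samples
are small and untied (scipy), otherwise the normal approximation with
continuity and tie correction. The Hodges-Lehmann estimator is the median
of all pairwise differences x_i - y_j; its CI is obtained by inverting the
U test — exactly via the partition-count null distribution of U for small
samples, else via the normal approximation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 10_000  # largest m*n for which the exact null CDF is used


@dataclasses.dataclass
class GroupTestResult:
    """Two-sided Mann-Whitney comparison of group x vs group y."""

    u_statistic: float
    p_value: float
    hl_shift: float        # median of pairwise differences x_i - y_j
    ci_low: float
    ci_high: float
    n_x: int
    n_y: int
    method: str            # "exact" | "asymptotic"


def _exact_u_cdf(m: int, n: int) -> np.ndarray:
    """P(U <= u) under H0 for sample sizes m, n, u = 0..m*n.

    Counts, via the standard partition recurrence, the number of
    arrangements of m 'x' ranks among m+n with each U value; equivalent to
    the coefficients of the Gaussian binomial [m+n choose m]_q.
    """
    # DP over the recurrence f_{i,j}(u) = f_{i,j-1}(u) + f_{i-1,j}(u - j)
    prev = {(0, j): np.array([1.0]) for j in range(n + 1)}
    for i in range(1, m + 1):
        cur = {}
        row0 = np.array([1.0])
        cur[(i, 0)] = row0
        for j in range(1, n + 1):
            a = cur[(i, j - 1)]
            b = prev[(i - 1, j)]
            size = i * j + 1
            arr = np.zeros(size)
            arr[: a.size] += a          # x_i after all remaining y: U contribution 0 path
            arr[j : j + b.size] += b    # shift by j
            cur[(i, j)] = arr
        prev = cur
    counts = prev[(m, n)]
    cdf = np.cumsum(counts)
    return cdf / cdf[-1]


def mann_whitney_hl(x, y, *, alpha: float = 0.05) -> GroupTestResult:
    """Two-sided Mann-Whitney U test with Hodges-Lehmann shift and CI.

    Returns the U statistic of ``x`` (number of (i, j) pairs with
    x_i > y_j, plus half-ties), the two-sided p, the Hodges-Lehmann
    estimate median(x_i - y_j) and its (1 - alpha) confidence interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    m, n = x.size, y.size

    has_ties = np.unique(np.concatenate([x, y])).size < m + n
    exact = (m * n <= EXACT_LIMIT) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    p = float(min(res.pvalue, 1.0))

    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))

    # CI by test inversion: the shift values delta for which H0: shift=delta
    # is not rejected at level alpha are an interval of order statistics of
    # the pairwise differences.
    mn = m * n
    if exact:
        cdf = _exact_u_cdf(m, n)
        # largest k with P(U <= k) <= alpha/2
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right") - 1)
    else:
        mu = mn / 2.0
        sigma = math.sqrt(mn * (m + n + 1) / 12.0)
        k = int(math.floor(mu + sps.norm.ppf(alpha / 2.0) * sigma))
    # CI = [D_(k+1), D_(mn-k)] in 1-indexed order statistics of the
    # pairwise differences (the shifts at which the level-alpha test does
    # not reject); same convention as R's wilcox.test conf.int.
    k = int(np.clip(k, 0, (mn - 1) // 2))
    lo, hi = diffs[k], diffs[mn - 1 - k]
    return GroupTestResult(u, p, hl, float(lo), float(hi), m, n, method)


def pearson_log10(x, y) -> float:
    """Pearson correlation of log10-transformed positive values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log10 correlation requires positive values")
    return float(sps.pearsonr(np.log10(x), np.log10(y)).statistic)
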