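"""Two-sided rank-sum (Mann-Whitney/Wilcoxon) test with an exact midrank path.

The exact path computes the full permutation distribution of the rank sum of
the smaller-design group over all C(N, n1) subset assignments of the pooled
observations, handling ties through midranks: midranks are doubled to
integers and the distribution of their subset sums is built by dynamic
programming. The two-sided p-value is twice the smaller tail probability
(point included), capped at 1 — so two identical samples give p = 1 and the
most extreme separation of n-vs-m gives p = 2/C(n+m, n).

Above ``exact_max_n`` observations in the smaller group the standard
tie-corrected, continuity-corrected normal approximation is used.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: largest min-group size for which the exact permutation distribution is used
EXACT_MAX_N = 10


@dataclass
class RankSumResult:
    statistic: float  # rank sum (midranks) of the first sample
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_x: int
    n_y: int


def rank_sum_test(x, y, exact_max_n: int = EXACT_MAX_N) -> RankSumResult:
    """Two-sided rank-sum test of ``x`` vs ``y``.

    Exact permutation p-value when ``min(len(x), len(y)) <= exact_max_n``,
    continuity- and tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    if min(n1, n2) <= exact_max_n:
        p = _exact_two_sided_p(ranks, n1, w)
        method = "exact"
    else:
        p = _normal_approx_two_sided_p(pooled, ranks, n1, n2, w)
        method = "normal_approx"
    return RankSumResult(statistic=w, p_value=p, method=method, n_x=n1, n_y=n2)


def _exact_two_sided_p(ranks: np.ndarray, n1: int, w: float) -> float:
    """Exact two-sided p over all subset assignments of the pooled midranks."""
    d = np.rint(2.0 * ranks).astype(np.int64)  # doubled midranks are integers
    n = d.size
    s_obs = int(round(2.0 * w))
    s_max = int(np.sort(d)[-n1:].sum())
    # f[j, s] = number of size-j subsets of the values seen so far with sum s
    f = np.zeros((n1 + 1, s_max + 1))
    f[0, 0] = 1.0
    for v in d:
        v = int(v)
        for j in range(n1, 0, -1):
            f[j, v:] += f[j - 1, : s_max + 1 - v]
    dist = f[n1]
    total = dist.sum()
    p_le = dist[: s_obs + 1].sum() / total
    p_ge = dist[s_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_approx_two_sided_p(
    pooled: np.ndarray, ranks: np.ndarray, n1: int, n2: int, w: float
) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all observations identical
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))
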