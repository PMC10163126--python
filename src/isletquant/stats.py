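"""Donor-level inferential comparisons.

Rank-based throughout, matching standard practice for small, skewed
histopathology samples: Kruskal-Wallis across groups with Dunn's pairwise
post-hoc z-tests (Bonferroni-adjusted), the Wilcoxon signed-rank test for
paired ICI/IDI comparisons within donors, and Spearman rank correlation.
The omnibus and paired tests delegate to scipy; Dunn's procedure is computed
here (rank sums on the pooled tie-corrected ranking) since scipy does not
ship it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "kgroup_rank_test", "paired_signed_rank", "rank_correlation"]


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``pairwise`` maps (group_i, group_j) -> Bonferroni-adjusted p value for
    post-hoc comparisons; empty when not applicable.
    """

    statistic: float
    p_value: float
    method: str
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)


def kgroup_rank_test(values_by_group: dict[str, "np.ndarray | list"]) -> TestResult:
    """Kruskal-Wallis test with Dunn's pairwise post-hoc comparisons.

    ``values_by_group`` maps group label -> donor-level values (each group
    non-empty).  The omnibus statistic is tie-corrected; pairwise z tests use
    the pooled mean ranks with the classic tie correction and Bonferroni
    adjustment over all pairs (capped at 1).
    """
    groups = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, s in zip(groups, samples):
        if s.size == 0:
            raise ValueError(f"group {g!r} has no values")

    stat, p = sps.kruskal(*samples)

    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    pos = 0
    for g, s in zip(groups, samples):
        mean_ranks[g] = float(ranks[pos:pos + s.size].mean())
        sizes[g] = s.size
        pos += s.size

    pairs = list(itertools.combinations(groups, 2))
    raw, adj = {}, {}
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    for gi, gj in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        if se == 0:
            raw[(gi, gj)] = 1.0
        else:
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            raw[(gi, gj)] = float(2.0 * sps.norm.sf(abs(z)))
        adj[(gi, gj)] = min(1.0, raw[(gi, gj)] * len(pairs))
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="kruskal-wallis + dunn (bonferroni)",
                      pairwise=adj, pairwise_raw=raw)


def paired_signed_rank(
    x, y, zero_method: str = "wilcox", alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test for paired samples.

    Exact null distribution for n <= 25 non-zero pairs (no ties among
    absolute differences), normal approximation with tie correction above.
    Zero differences are dropped by default (``wilcox``); ``pratt`` keeps
    them in the ranking.  All pairs equal yields p = 1 under the drop-zeros
    policy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = x - y
    nonzero = d[d != 0]
    if zero_method == "wilcox" and nonzero.size == 0:
        return TestResult(statistic=0.0, p_value=1.0,
                          method="wilcoxon signed-rank (all differences zero)")
    n_eff = nonzero.size if zero_method == "wilcox" else d.size
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (n_eff <= 25 and not has_ties and zero_method == "wilcox") \
        else "approx"
    res = sps.wilcoxon(x, y, zero_method=zero_method, alternative=alternative,
                       correction=False, method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"wilcoxon signed-rank ({method}, {zero_method})")


def rank_correlation(
    x, y, method: str = "t-approx", n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation with tie-aware ranks.

    Returns (rho, p).  ``method='t-approx'`` uses the t approximation;
    ``'permutation'`` permutes y ``n_perm`` times (two-sided).  A constant
    input vector has undefined correlation -> (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = sps.spearmanr(x, y)
    if method == "t-approx":
        return float(rho), float(p)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            hits += 1
    return float(rho), (hits + 1) / (n_perm + 1)
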