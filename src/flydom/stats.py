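"""Exact nonparametric tests used by the peri-event and outcome analyses.

The signed-rank and rank-sum tests here compute *exact* two-sided
p-values by dynamic programming over mid-ranked, tie-aware rank sums for
small samples, switching to the normal approximation with continuity and
tie corrections for larger ones.  Zero differences are dropped before
ranking (the classic Wilcoxon treatment).  The exact two-sided p-value
is ``min(1, 2 * min(P(W <= w), P(W >= w)))`` under the permutation null.

Binomial, Fisher, Kruskal–Wallis and chi-square tests are delegated to
scipy; only the rank tests need the tie-exact treatment implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SignedRankResult",
    "RankSumResult",
    "signed_rank_test",
    "rank_sum_test",
    "stars",
]

#: Largest n for which the exact signed-rank null is enumerated.
SIGNED_RANK_EXACT_MAX_N = 25
#: Largest combined N for which the exact rank-sum null is enumerated.
RANK_SUM_EXACT_MAX_N = 30


def stars(p: Optional[float]) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p is None or not np.isfinite(p):
        return "n.s."
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class SignedRankResult:
    w_plus: float
    n_nonzero: int
    p_two_sided: float
    direction: str  # "pre_greater" | "post_greater" | "none" (sign of diffs)
    method: str


@dataclass(frozen=True)
class RankSumResult:
    rank_sum_x: float
    n_x: int
    n_y: int
    p_value: float
    alternative: str
    method: str


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks scaled by two so tied mid-ranks become exact integers."""
    ranks2 = np.rint(2.0 * sps.rankdata(values)).astype(np.int64)
    return ranks2


def _signed_rank_null_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled ``W+`` over all sign assignments.

    ``counts[s]`` = number of the ``2**n`` sign vectors whose positive-part
    rank sum (doubled scale) equals ``s``.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def signed_rank_test(
    diffs: Sequence[float], exact_max_n: int = SIGNED_RANK_EXACT_MAX_N
) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped before ranking; ties get mid-ranks.  Exact null by
    DP for up to ``exact_max_n`` non-zero differences, else a normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return SignedRankResult(0.0, 0, 1.0, "none", "degenerate")
    ranks2 = _doubled_midranks(np.abs(d))
    w_plus2 = int(ranks2[d > 0].sum())
    w_plus = w_plus2 / 2.0
    w_minus = ranks2[d < 0].sum() / 2.0
    if w_plus > w_minus:
        direction = "post_greater"
    elif w_plus < w_minus:
        direction = "pre_greater"
    else:
        direction = "none"

    if n <= exact_max_n:
        counts = _signed_rank_null_counts(ranks2)
        total = counts.sum()
        p_le = counts[: w_plus2 + 1].sum() / total
        p_ge = counts[w_plus2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = ranks2.sum() / 2.0 / 2.0  # n(n+1)/4 on the natural scale
        # Var(W+) = sum(r_i^2)/4 under random signs (tie-aware mid-ranks)
        var = float(np.sum((ranks2 / 2.0) ** 2)) / 4.0
        if var == 0:
            return SignedRankResult(w_plus, n, 1.0, direction, "degenerate")
        z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "normal"
    return SignedRankResult(w_plus, n, float(p), direction, method)


def _rank_sum_null_counts(ranks2: np.ndarray, n_x: int) -> np.ndarray:
    """Counts of doubled rank-sums over all size-``n_x`` subsets.

    ``counts[s]`` = number of subsets of size ``n_x`` whose doubled rank
    sum equals ``s``.
    """
    total = int(ranks2.sum())
    counts = np.zeros((n_x + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n_x, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    return counts[n_x]


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = RANK_SUM_EXACT_MAX_N,
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann–Whitney) test with a tie-exact small-n null.

    ``alternative='less'`` tests whether ``x`` is stochastically smaller.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = x.size, y.size
    if n_x == 0 or n_y == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks2 = _doubled_midranks(pooled)
    w_x2 = int(ranks2[:n_x].sum())

    if n_x + n_y <= exact_max_n:
        counts = _rank_sum_null_counts(ranks2, n_x)
        total = counts.sum()
        p_le = counts[: w_x2 + 1].sum() / total
        p_ge = counts[w_x2:].sum() / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        n = n_x + n_y
        w_x = w_x2 / 2.0
        mu = n_x * (n + 1) / 2.0
        tie_term = 0.0
        _, t_counts = np.unique(ranks2, return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return RankSumResult(w_x2 / 2.0, n_x, n_y, 1.0, alternative, "degenerate")
        sd = np.sqrt(var)
        if alternative == "less":
            z = (w_x - mu + 0.5) / sd
            p = float(sps.norm.cdf(z))
        elif alternative == "greater":
            z = (w_x - mu - 0.5) / sd
            p = float(sps.norm.sf(z))
        else:
            z = (abs(w_x - mu) - 0.5) / sd
            p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        method = "normal"
    return RankSumResult(w_x2 / 2.0, n_x, n_y, float(p), alternative, method)
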