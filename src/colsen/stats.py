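"""Shared statistical helpers: rank-sum tests, exact tests, BH correction.

The exact rank-sum path enumerates all group assignments (tie-aware via
midranks), used for small samples; larger samples fall back to the
tie-corrected normal approximation.  Fisher's exact test and the
hypergeometric tail come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    pvalue: float
    method: str  # "exact" or "normal"
    n1: int
    n2: int


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def rank_sum_test(
    x, y, alternative: str = "two-sided", exact_max_n: int = EXACT_RANKSUM_MAX_N
) -> RankSumResult:
    """Mann-Whitney / Wilcoxon rank-sum test.

    Exact tie-aware enumeration over all C(n1+n2, n1) group assignments when
    the combined sample size is at most ``exact_max_n``; otherwise the
    tie-corrected normal approximation (scipy, with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if n1 + n2 <= exact_max_n:
        combined = np.concatenate([x, y])
        ranks = sps.rankdata(combined)
        u_obs = _u_from_ranks(float(ranks[:n1].sum()), n1)
        center = n1 * n2 / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_from_ranks(float(ranks[list(idx)].sum()), n1)
            total += 1
            if alternative == "two-sided":
                hit = abs(u - center) >= dev_obs - 1e-12
            elif alternative == "greater":  # x tends larger
                hit = u >= u_obs - 1e-12
            elif alternative == "less":
                hit = u <= u_obs + 1e-12
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
            count += hit
        return RankSumResult(u_obs, count / total, "exact", n1, n2)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), "normal", n1, n2)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table."""
    _, p = sps.fisher_exact(np.asarray(table, dtype=int), alternative=alternative)
    return float(p)


def hypergeom_upper_tail(k: int, n_draws: int, n_marked: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, n_marked, n_draws)."""
    return float(sps.hypergeom.sf(k - 1, universe, n_marked, n_draws))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
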