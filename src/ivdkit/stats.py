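"""Nonparametric group comparisons with false-discovery-rate control.

Two-sided Mann-Whitney U tests with midrank handling of ties.  For small
samples the p value is exact: all C(n1+n2, n1) allocations of the pooled
(mid)ranks are enumerated, which remains valid under ties where the classic
null tables and scipy's exact method do not apply.  Larger samples use the
tie-corrected normal approximation with continuity correction.  Families of
p values are corrected by the Benjamini-Hochberg step-up procedure; the
"corrected threshold" it reports (the largest rejected p) is a
data-dependent output of each analysis, not a constant of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy.stats import rankdata

DEFAULT_EXACT_CAP = 64  # enumerate exactly when n1*n2 <= cap


@dataclass(frozen=True)
class ComparisonResult:
    endpoint: str
    label_x: str
    label_y: str
    n_x: int
    n_y: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "degenerate"
    bh_adjusted_p: float | None = None
    significant: bool | None = None


def _u_from_ranks(rank_sum_x: float, n_x: int) -> float:
    return rank_sum_x - n_x * (n_x + 1) / 2.0


@lru_cache(maxsize=16)
def _subset_indices(n: int, n_x: int) -> np.ndarray:
    """All C(n, n_x) index subsets as an array (cached across calls)."""
    return np.array(list(combinations(range(n), n_x)), dtype=np.intp)


def _exact_p(ranks: np.ndarray, n_x: int, u_obs: float) -> float:
    """Two-sided exact p: twice the smaller one-sided tail of U, capped at 1.

    The full permutation distribution of U is enumerated over all
    C(n, n_x) allocations of the pooled midranks; under ties it is not
    symmetric, so both tails are computed explicitly.
    """
    idx = _subset_indices(ranks.size, n_x)
    u1 = ranks[idx].sum(axis=1) - n_x * (n_x + 1) / 2.0
    lo = int(np.sum(u1 <= u_obs + 1e-9))
    hi = int(np.sum(u1 >= u_obs - 1e-9))
    return min(1.0, 2.0 * min(lo, hi) / comb(ranks.size, n_x))


def _normal_p(ranks: np.ndarray, n_x: int, u: float) -> float:
    n = ranks.size
    n_y = n - n_x
    mu = n_x * n_y / 2.0
    # tie correction from the multiplicity of each rank value
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0))))


def mann_whitney_u(
    x,
    y,
    endpoint: str = "",
    label_x: str = "x",
    label_y: str = "y",
    exact_cap: int = DEFAULT_EXACT_CAP,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u1 = _u_from_ranks(float(ranks[: x.size].sum()), x.size)
    if np.all(pooled == pooled[0]):
        return ComparisonResult(
            endpoint, label_x, label_y, x.size, y.size, u1, 1.0, "degenerate"
        )
    if x.size * y.size <= exact_cap:
        p = _exact_p(ranks, x.size, u1)
        method = "exact"
    else:
        p = _normal_p(ranks, x.size, u1)
        method = "normal_approx"
    return ComparisonResult(endpoint, label_x, label_y, x.size, y.size, u1, p, method)


@dataclass(frozen=True)
class BhResult:
    adjusted_p: np.ndarray
    reject: np.ndarray
    corrected_threshold: float | None  # largest rejected raw p, if any
    n_rejected: int
    alpha: float


def benjamini_hochberg(p_values, alpha: float = 0.05) -> BhResult:
    """Benjamini-Hochberg step-up FDR correction.

    Sorts the m p values ascending, finds the largest k with
    p(k) <= k*alpha/m, rejects hypotheses 1..k, and reports monotone
    adjusted p values p_adj(i) = min_{j>=i} m*p(j)/j.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return BhResult(np.array([]), np.array([], dtype=bool), None, 0, alpha)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    passed = ranked <= np.arange(1, m + 1) * alpha / m
    k = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    adjusted = np.empty(m)
    adjusted[order] = adj
    reject = np.empty(m, dtype=bool)
    reject[order] = reject_sorted
    return BhResult(
        adjusted_p=adjusted,
        reject=reject,
        corrected_threshold=float(ranked[k - 1]) if k else None,
        n_rejected=k,
        alpha=alpha,
    )


def apply_bh(results: list[ComparisonResult], alpha: float = 0.05) -> list[ComparisonResult]:
    """Return comparisons annotated with BH-adjusted p values (study-wide family)."""
    if not results:
        return []
    bh = benjamini_hochberg([r.p_value for r in results], alpha=alpha)
    out = []
    for r, ap, rej in zip(results, bh.adjusted_p, bh.reject):
        out.append(
            ComparisonResult(
                r.endpoint, r.label_x, r.label_y, r.n_x, r.n_y,
                r.u_statistic, r.p_value, r.method,
                bh_adjusted_p=float(ap), significant=bool(rej),
            )
        )
    return out
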