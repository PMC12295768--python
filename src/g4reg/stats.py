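"""Statistical core: exact Fisher, rank tests, BH adjustment, permutation p.

``fisher_exact_two_sided`` follows the minimum-likelihood convention (the
one R's ``fisher.test`` uses): the two-sided p is the sum of hypergeometric
point probabilities, over all tables with the observed margins, that do not
exceed the observed table's probability by more than a relative tolerance
of 1e-7. Point probabilities are handled in log space so p-values down to
~1e-100 are representable without underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "wilcoxon_rank_sum",
    "spearman_correlation",
    "bh_adjust",
    "empirical_p",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Row 1 = condition of interest, column 1 = success."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


_REL_TOL = 1e-7  # min-likelihood inclusion tolerance, R convention


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test, minimum-likelihood convention.

    Sums P(X = k) over all k with the observed margins for which
    ``P(k) <= (1 + 1e-7) * P(observed)``, computed via log-space
    hypergeometric point probabilities.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1 = a + c
    n = a + b + c + d
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        warnings.warn("degenerate margin in 2x2 table; p = 1", stacklevel=2)
        return TestResult(np.nan, 1.0, "fisher_exact_two_sided", n)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    support = np.arange(lo, hi + 1)
    logpmf = sps.hypergeom.logpmf(support, n, col1, row1)
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + np.log1p(_REL_TOL)
    if keep.all():
        return TestResult(float(a), 1.0, "fisher_exact_two_sided", n)
    p = float(np.exp(logsumexp(logpmf[keep])))
    return TestResult(float(a), min(p, 1.0), "fisher_exact_two_sided", n)


def wilcoxon_rank_sum(
    x, y, alternative: str = "two_sided", exact_max_n: int = 50
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) with average ranks for ties.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction (the R ``wilcox.test`` switching behaviour). Degenerate data
    (every value identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    n = x.size + y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return TestResult(u, 1.0, "wilcoxon_rank_sum[degenerate]", n)
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return TestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), f"wilcoxon_rank_sum[{method}]", n
    )


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation (Pearson of average ranks, t-approx p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("zero rank variance; Spearman undefined", stacklevel=2)
        return TestResult(np.nan, np.nan, "spearman[undefined]", int(x.size))
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman", int(x.size))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def empirical_p(observed: float, null_samples, alternative: str = "greater") -> float:
    """Add-one permutation p-value: ``(#{null as extreme} + 1) / (m + 1)``."""
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise ValueError("need >=1 null sample")
    if alternative == "greater":
        k = int(np.count_nonzero(null >= observed))
    elif alternative == "less":
        k = int(np.count_nonzero(null <= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (k + 1) / (null.size + 1)
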