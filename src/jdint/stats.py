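"""Nonparametric tests used throughout the interface analysis.

The paired comparisons (JD vs C-terminal residue counts; wt vs exp forms)
use an exact two-sided sign test; independent samples use a Mann-Whitney U
test; per-residue occupancy profiles are compared with Pearson correlation
plus an ordinary least-squares line. Significance is conventionally taken
at 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SignTestResult",
    "MannWhitneyResult",
    "CorrelationResult",
    "sign_test",
    "mann_whitney",
    "pearson_with_fit",
    "share",
]


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    n_ties: int
    p_value: float

    @property
    def n_effective(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def sign_test(n_pos: int, n_neg: int, n_ties: int = 0) -> SignTestResult:
    """Exact two-sided sign test on paired difference signs.

    Ties are excluded; with ``k = n_pos`` successes out of
    ``n = n_pos + n_neg`` trials under Binomial(n, 1/2), the two-sided
    p-value is the doubled smaller tail capped at 1:
    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))``, computed by exact
    binomial summation (no normal approximation).
    """
    if min(n_pos, n_neg, n_ties) < 0:
        raise ValueError("counts must be non-negative")
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("sign test undefined with no non-tied pairs")
    k = n_pos
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    p = min(1.0, 2.0 * min(lower, upper))
    return SignTestResult(n_pos=n_pos, n_neg=n_neg, n_ties=n_ties, p_value=float(p))


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Uses the exact null distribution when both samples have at most 12
    observations and the pooled data are tie-free; otherwise the normal
    approximation with midrank tie correction. Returns the U statistic of
    the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= 12 and b.size <= 12 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue),
                             method=method)


def pearson_with_fit(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p and the OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(r=float(r), p_value=float(p),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept), n=int(x.size))


def share(count: int, total: int) -> float:
    """Percentage ``100 * count / total`` (e.g. 18 of 87 interactors -> 20.7)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must be in [0, total]")
    return 100.0 * count / total
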