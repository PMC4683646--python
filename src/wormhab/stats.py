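"""Plate-level group statistics.

The unit of replication is one assay plate's summary value (or one
experimental day's mean, for harsh touch).  Group contrasts use the
classical pooled-variance unpaired two-tailed t-test, cross-checked
with a Mann-Whitney U test; p-values are reported uncorrected, with an
advisory Bonferroni flag for a stated number of comparisons (default
5, the most ever made for one group in this design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .core import WormhabError
from .simulate import HarshTouchDataset

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "t_test_unpaired",
    "mann_whitney_u",
    "harsh_day_means",
    "percent_reduction",
    "compare_groups",
]


@dataclass
class GroupSample:
    """One genotype/condition's per-plate (or per-day) datum values."""

    label: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise WormhabError("GroupSample data must be one-dimensional")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def mean(self) -> float:
        return float(self.data.mean())

    @property
    def sem(self) -> float:
        if self.n < 2:
            return math.nan
        return float(self.data.std(ddof=1) / math.sqrt(self.n))


def t_test_unpaired(a: GroupSample, b: GroupSample) -> tuple[float, float]:
    """Student's pooled-variance unpaired two-tailed t-test.

    Returns (t, p) with df = n_a + n_b - 2.  Degenerate limit: zero
    pooled variance gives p = 1 for equal means and p = 0 otherwise.
    """
    if a.n < 2 or b.n < 2:
        raise WormhabError("t-test requires n >= 2 in both groups")
    na, nb = a.n, b.n
    df = na + nb - 2
    va = a.data.var(ddof=1)
    vb = b.data.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = a.mean - b.mean
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[float, ...]:
    """Number of tie-free rank arrangements giving each U value for
    sample sizes (n1, n2), by dynamic programming over pooled positions.

    U is the count of (a, b) pairs with a ranked above b; placing an 'a'
    at pooled position ``pos`` with j a's used so far adds the pos - j
    b's already placed.
    """
    umax = n1 * n2
    dp = np.zeros((n1 + 1, umax + 1))
    dp[0, 0] = 1.0
    for pos in range(1, n1 + n2 + 1):
        ndp = np.zeros_like(dp)
        for j in range(0, min(n1, pos) + 1):
            b_used = pos - j
            if b_used < 0 or b_used > n2:
                continue
            if b_used >= 1:  # position holds a 'b'
                ndp[j] += dp[j]
            if j >= 1:  # position holds an 'a'; U gains the b's before it
                shift = pos - j
                ndp[j, shift:] += dp[j - 1, : umax + 1 - shift]
        dp = ndp
    return tuple(dp[n1])


def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    counts = np.asarray(_u_counts(n1, n2))
    return np.cumsum(counts) / counts.sum()


def mann_whitney_u(a: GroupSample, b: GroupSample) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns (U, p) where U is the statistic for sample ``a``.  For
    min(n) <= 8 with no ties the p-value is exact: twice the smaller
    tail of the enumerated U distribution, capped at 1.  Otherwise the
    normal approximation with tie correction and continuity correction
    is used.
    """
    if a.n < 2 or b.n < 2:
        raise WormhabError("Mann-Whitney requires n >= 2 in both groups")
    xa, xb = a.data, b.data
    n1, n2 = a.n, b.n
    pooled = np.concatenate([xa, xb])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if min(n1, n2) <= 8 and not has_ties:
        cdf = _exact_u_cdf(n1, n2)
        u = int(round(u1))
        lower = cdf[u]
        upper = 1.0 - (cdf[u - 1] if u >= 1 else 0.0)
        p = min(1.0, 2.0 * min(lower, upper))
        return float(u1), float(p)

    mu = n1 * n2 / 2.0
    nn = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if var <= 0:
        return float(u1), 1.0
    z = (u1 - mu - math.copysign(0.5, u1 - mu)) / math.sqrt(var) if u1 != mu else 0.0
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(u1), min(p, 1.0)


def harsh_day_means(ds: HarshTouchDataset) -> GroupSample:
    """One datum per experimental day: the day's mean bend count."""
    if not ds.day_counts:
        raise WormhabError("harsh-touch dataset has no days")
    means = [float(np.mean(day)) for day in ds.day_counts]
    return GroupSample(label=ds.genotype, data=np.asarray(means))


def percent_reduction(a: GroupSample, b: GroupSample) -> float:
    """Reduction of b relative to a: 100*(mean_a - mean_b)/mean_a.

    Negative when b exceeds a.
    """
    ma = a.mean
    if ma == 0:
        raise WormhabError("reference group mean is zero")
    return 100.0 * (ma - b.mean) / ma


@dataclass
class ComparisonResult:
    """Two-group contrast with both tests and the Bonferroni note."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_stat: float
    p_t: float
    u_stat: float
    p_u: float
    percent_change: float
    bonferroni_m: int
    significant_after_bonferroni: bool


def compare_groups(
    a: GroupSample,
    b: GroupSample,
    m_comparisons: int = 5,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Full contrast between two group samples.

    ``percent_change`` is 100*(mean_b - mean_a)/mean_a.  The Bonferroni
    flag marks whether the t-test p-value survives correction for
    ``m_comparisons`` comparisons at ``alpha``; reported p-values
    themselves are uncorrected.
    """
    if a.n < 2 or b.n < 2:
        raise WormhabError("group comparison requires n >= 2 in both groups")
    t, p_t = t_test_unpaired(a, b)
    u, p_u = mann_whitney_u(a, b)
    ma = a.mean
    pc = math.nan if ma == 0 else 100.0 * (b.mean - ma) / ma
    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        n_a=a.n,
        n_b=b.n,
        mean_a=ma,
        mean_b=b.mean,
        sem_a=a.sem,
        sem_b=b.sem,
        t_stat=t,
        p_t=p_t,
        u_stat=u,
        p_u=p_u,
        percent_change=pc,
        bonferroni_m=m_comparisons,
        significant_after_bonferroni=bool(p_t < alpha / m_comparisons),
    )
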