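"""Clinical trial statistics: Fisher's exact test, Mann-Whitney U, sample size.

These are the statistics behind the trial's baseline and outcome tables and
its design: exact two-sided Fisher tests on 2x2 tables of nominal
variables, rank tests on continuous variables, and the two-proportion
normal-approximation sample-size formula with dropout inflation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Relative tolerance for declaring two hypergeometric point probabilities
#: tied in the two-sided Fisher rule.
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows = randomized group, columns = outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Conditional on both margins, the point probability of every table in
    the support is computed and the two-sided p is the sum of point
    probabilities not exceeding the observed one (with a small relative
    tolerance for floating-point ties).  A zero row or column margin gives
    p = 1 by convention, with a warning.

    ``table`` may be a ContingencyTable2x2 or any 2x2 array-like.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    ContingencyTable2x2(int(a), int(b), int(c), int(d))
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    include = pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-sided p-value.

    The p-value is exact (full enumeration) when the combined sample size
    is at most 12 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections is used.  Identical constant
    samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(x.size * y.size / 2), 1.0
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Two-proportion sample-size problem with anticipated attrition."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80
    loss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p1 == self.p2:
            raise ValueError("p1 and p2 must differ (required n is infinite)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 <= self.loss < 1:
            raise ValueError("loss must lie in [0, 1)")


def sample_size_two_proportions(spec: SampleSizeSpec) -> tuple[int, int, int]:
    """Evaluable n per group, total, and enrollment inflated for attrition.

    Normal-approximation formula with pooled variance under the null and no
    continuity correction:

        n = (z_{1-a/2} sqrt(2 p̄ q̄) + z_{power} sqrt(p1 q1 + p2 q2))^2 / (p1-p2)^2

    rounded to the nearest integer per group (not the ceiling — this
    matches designs that quote 23/group for 70% vs 30% at alpha 0.05,
    power 0.80).  Enrollment is floor(n_total / (1 - loss)).
    """
    p1, p2 = spec.p1, spec.p2
    pbar = (p1 + p2) / 2.0
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_b * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    n_exact = (num / (p1 - p2)) ** 2
    n_per_group = int(round(n_exact))
    n_total = 2 * n_per_group
    n_enrolled = int(math.floor(n_total / (1.0 - spec.loss)))
    return n_per_group, n_total, n_enrolled
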