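"""Exact contingency-table tests and small statistical utilities.

The localization-fraction comparisons in the assays this package supports
are scored with Fisher's exact test on 2x2 tables, and the rare-event loss
rates call for exact (Clopper-Pearson) binomial intervals.  Both are
implemented here so that the two-sided convention and the interval method
are explicit and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "ExactTestResult",
    "fisher_exact",
    "binomial_ci",
    "mean_sem",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"table entry {name}={v} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table: at least one entry must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class ExactTestResult:
    """Two-sided exact-test p-value and the sample odds ratio.

    ``odds_ratio`` is (a*d)/(b*c); it is ``inf`` when b*c == 0 while
    a*d > 0, and ``nan`` when both products vanish.  ``method`` records
    the two-sided convention used.
    """

    p_two_sided: float
    odds_ratio: float
    method: str = "fisher-exact/probability-mass"


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, k: int) -> np.ndarray:
    """log P(A = a) for the hypergeometric table distribution with row sums
    r1, r2 and first-column sum k."""
    n = r1 + r2

    def logC(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return logC(r1, a) + logC(r2, k - a) - logC(n, k)


def fisher_exact(table: ContingencyTable2x2) -> ExactTestResult:
    """Two-sided Fisher's exact test for a 2x2 table.

    The two-sided p-value follows the probability-mass rule: it sums the
    conditional hypergeometric probabilities of every table sharing the
    observed margins whose probability does not exceed the observed
    table's (ties admitted within relative tolerance 1e-12).  Probabilities
    are evaluated in log space with log-gamma so that totals of several
    thousand do not overflow.
    """
    if isinstance(table, (list, tuple, np.ndarray)):
        arr = np.asarray(table, dtype=np.int64)
        table = ContingencyTable2x2(*arr.ravel().tolist())
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, k = a + b, c + d, a + c

    lo, hi = max(0, k - r2), min(k, r1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, k)
    logp_obs = _log_hypergeom_pmf(np.array([a]), r1, r2, k)[0]
    # include as-or-less-probable tables; the slack absorbs round-off on exact ties
    mask = logp <= logp_obs + math.log1p(1e-12) + 1e-12 * abs(logp_obs)
    p = float(np.exp(logp[mask]).sum())
    p = min(1.0, p)

    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = math.inf
    else:
        odds = math.nan
    return ExactTestResult(p_two_sided=p, odds_ratio=odds)


def binomial_ci(events: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson confidence interval for an event probability.

    Returns (lower, upper) on the probability scale.  The lower bound is
    exactly 0 when ``events == 0`` and the upper exactly 1 when
    ``events == n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    alpha = 1.0 - level
    lo, hi = proportion_confint(events, n, alpha=alpha, method="beta")
    # statsmodels returns nan at the boundary cases; the exact bounds are 0/1
    lo = 0.0 if events == 0 or not np.isfinite(lo) and events == 0 else float(lo)
    hi = 1.0 if events == n or not np.isfinite(hi) and events == n else float(hi)
    if not np.isfinite(lo):
        lo = 0.0
    return lo, hi


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (sd/sqrt(n), ddof=1).

    With fewer than two values the sem is undefined and returned as nan.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mean_sem requires at least one value")
    mean = float(x.mean())
    if x.size < 2:
        return mean, math.nan
    sem = float(x.std(ddof=1) / math.sqrt(x.size))
    return mean, sem
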