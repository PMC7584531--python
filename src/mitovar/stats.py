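"""Exact 2x2 association statistics and summary-statistic t-tests.

Conventions follow common clinical-genetics reporting practice:

* Fisher's exact test is the two-sided point-probability ("minimum
  likelihood") test, computed on the raw, uncorrected counts.
* The odds ratio uses the Haldane–Anscombe correction — 0.5 added to
  *all four* cells — whenever any cell is zero. The correction affects
  the OR and its confidence interval only, never the Fisher p-value.
* Confidence intervals are Woolf (logit) intervals,
  ``exp(ln OR ± z·SE)`` with ``SE = sqrt(1/a + 1/b + 1/c + 1/d)`` over
  the (possibly corrected) cells and z the exact normal quantile.
* The two-sample t-test is the pooled-variance test by default
  (Welch available via a flag), accepting summary statistics so that
  published mean ± SD pairs can be re-tested directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats as _sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with exposure in rows, group in columns:
    a = exposed cases, b = unexposed cases,
    c = exposed controls, d = unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all four cells are zero")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def has_zero_cell(self) -> bool:
        return 0 in self.cells


@dataclass(frozen=True)
class AssociationResult:
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_applied: bool
    table: ContingencyTable2x2 | None = None

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value out of range: {self.p_value}")
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("confidence bounds do not bracket the odds ratio")


def _as_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    return ContingencyTable2x2(*t)


def fisher_exact_two_sided(t: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher exact p on the raw counts.

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability does not exceed the observed
    table's (with a ~1e-7 relative tolerance for floating-point ties).
    """
    t = _as_table(t)
    p = _sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return min(float(p), 1.0)


def _corrected_cells(t: ContingencyTable2x2) -> tuple[tuple[float, ...], bool]:
    if t.has_zero_cell:
        return tuple(x + 0.5 for x in t.cells), True
    return tuple(float(x) for x in t.cells), False


def odds_ratio(t: ContingencyTable2x2 | tuple) -> tuple[float, bool]:
    """(odds ratio, haldane_applied). With any zero cell, 0.5 is added
    to all four cells before forming (a·d)/(b·c)."""
    t = _as_table(t)
    (a, b, c, d), corrected = _corrected_cells(t)
    return (a * d) / (b * c), corrected


def woolf_ci(t: ContingencyTable2x2 | tuple, level: float = 0.95
             ) -> tuple[float, float]:
    """Woolf (logit) confidence interval, on the same (possibly
    Haldane-corrected) cells as the odds ratio."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    t = _as_table(t)
    (a, b, c, d), _ = _corrected_cells(t)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(_sps.norm.ppf(1 - (1 - level) / 2))
    return math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def associate(t: ContingencyTable2x2 | tuple, level: float = 0.95
              ) -> AssociationResult:
    """Full association summary: Fisher p, (corrected) OR and Woolf CI."""
    t = _as_table(t)
    or_, corrected = odds_ratio(t)
    lo, hi = woolf_ci(t, level)
    return AssociationResult(fisher_exact_two_sided(t), or_, lo, hi, corrected, t)


def pooled_t_test(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int,
                  equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Returns (t, df, two-sided p). Pooled-variance by default with
    df = n1 + n2 - 2; ``equal_var=False`` gives Welch. Two degenerate
    groups with equal means return t = 0, p = 1 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = _sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def counts_from_percent(pct: float, n: int) -> int:
    """Reconstruct a raw count from a printed percentage and group size.

    k = round(pct·n/100) with half-up rounding; warns (does not fail)
    when re-deriving the printed percent from k is inconsistent.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage out of range: {pct}")
    if n <= 0:
        raise ValueError(f"group size must be positive: {n}")
    k = math.floor(pct * n / 100 + 0.5)
    back = math.floor(100 * k / n + 0.5)
    if back != math.floor(pct + 0.5):
        warnings.warn(
            f"count {k}/{n} rounds back to {back}%, printed value was {pct}%",
            stacklevel=2,
        )
    return k
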