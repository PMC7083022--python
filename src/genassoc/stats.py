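"""Contingency-table statistics shared by every analysis stage.

Odds ratios carry Woolf (logit) 95% confidence intervals,
``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` with z the exact 97.5%
normal quantile.  When a table contains a zero cell the Gart-adjusted logit
interval is used instead: 0.5 is added to all four cells and the Woolf
formulas are applied to the adjusted cells, for the point estimate as well
as the interval.

Table orientation is fixed throughout the package: group 1 (rows ``a``,
``b``) holds the cases — or, in a case-only subgroup analysis, the class
listed first — and the "exposed" column holds the genotype or haplotype
category under test, so ``OR = (a*d) / (b*c)`` is the odds of the tested
category in group 1 relative to group 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Table2x2",
    "ORResult",
    "TestResult",
    "ZeroCellError",
    "woolf_or_ci",
    "gart_or_ci",
    "odds_ratio_ci",
    "pearson_chi2",
    "fisher_exact",
    "student_t",
    "bonferroni_threshold",
    "Z_975",
]

#: Exact standard-normal 97.5% quantile used for every 95% interval.
Z_975 = float(sps.norm.ppf(0.975))


class ZeroCellError(ValueError):
    """A Woolf interval was requested for a table with a zero cell; use
    :func:`gart_or_ci` (or :func:`odds_ratio_ci`, which dispatches)."""


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table of non-negative integer counts.

    ``a``: group-1 exposed, ``b``: group-1 unexposed, ``c``: group-2
    exposed, ``d``: group-2 unexposed (see module docstring for the
    orientation convention).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        for x in cells:
            if x != int(x) or x < 0:
                raise ValueError(f"cell counts must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return sum(self.cells)

    def has_zero_cell(self) -> bool:
        return 0 in self.cells

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swap_exposure(self) -> "Table2x2":
        """Exchange the exposed/unexposed columns (inverts the OR)."""
        return Table2x2(self.b, self.a, self.d, self.c)

    def swap_groups(self) -> "Table2x2":
        """Exchange the two rows (also inverts the OR)."""
        return Table2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class ORResult:
    """Odds-ratio point estimate with 95% logit confidence interval."""

    or_point: float
    ci_low: float
    ci_high: float
    z_quantile: float
    method: str  # "woolf" | "gart"
    adjusted_cells: tuple  # the four cell values the formulas actually used

    def __post_init__(self):
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("confidence interval does not bracket the point estimate")


@dataclass(frozen=True)
class TestResult:
    """Generic hypothesis-test result: statistic, df, two-sided p."""

    statistic: float
    df: Optional[int]
    p: float
    test_name: str

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p}")


def _logit_interval(a: float, b: float, c: float, d: float, method: str) -> ORResult:
    or_point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(or_point)
    return ORResult(
        or_point=or_point,
        ci_low=math.exp(log_or - Z_975 * se),
        ci_high=math.exp(log_or + Z_975 * se),
        z_quantile=Z_975,
        method=method,
        adjusted_cells=(a, b, c, d),
    )


def woolf_or_ci(t: Table2x2) -> ORResult:
    """Woolf odds ratio and 95% CI for a zero-free 2x2 table.

    Raises :class:`ZeroCellError` on any zero cell; use :func:`gart_or_ci`.
    """
    if t.has_zero_cell():
        raise ZeroCellError(
            f"table {t.cells} has a zero cell; use gart_or_ci (Gart-adjusted logit interval)"
        )
    return _logit_interval(*t.cells, method="woolf")


def gart_or_ci(t: Table2x2) -> ORResult:
    """Gart-adjusted logit interval: add 0.5 to all four cells, then Woolf.

    Requires at least one zero cell (a zero-free table should use the plain
    Woolf interval).  A table with an empty row or column has no defined
    odds ratio even after adjustment and is rejected.
    """
    if not t.has_zero_cell():
        raise ValueError(f"table {t.cells} has no zero cell; use woolf_or_ci")
    a, b, c, d = t.cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(f"table {t.cells} has an empty margin; odds ratio undefined")
    return _logit_interval(a + 0.5, b + 0.5, c + 0.5, d + 0.5, method="gart")


def odds_ratio_ci(t: Table2x2) -> ORResult:
    """Woolf OR/CI, falling back to the Gart adjustment on any zero cell."""
    return gart_or_ci(t) if t.has_zero_cell() else woolf_or_ci(t)


def pearson_chi2(table: Sequence) -> TestResult:
    """Pearson chi-square test of independence on an R x C count table.

    Classical ``sum (O-E)^2 / E`` with expectations from the margins,
    ``df = (R-1)(C-1)``, no continuity correction, upper-tail p.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table is degenerate: fewer than 2 non-empty rows or columns")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(statistic=float(chi2), df=int(df), p=float(p), test_name="pearson_chi2")


def fisher_exact(t: Table2x2) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    An empty margin gives p = 1 by convention.
    """
    a, b, c, d = t.cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return TestResult(statistic=float("nan"), df=None, p=1.0, test_name="fisher_exact")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(statistic=float("nan"), df=None, p=float(min(p, 1.0)),
                      test_name="fisher_exact")


def student_t(x: Sequence, y: Sequence, pooled: bool = True) -> TestResult:
    """Two-sided two-sample t test; pooled variance by default, Welch optional.

    Two zero-variance samples with equal means return t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2 if pooled else None
        return TestResult(statistic=0.0, df=df, p=1.0, test_name="student_t")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else None
    return TestResult(statistic=float(res.statistic), df=df, p=float(res.pvalue),
                      test_name="student_t" if pooled else "welch_t")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha/m.

    Reported to 4 significant digits (round-half-even); e.g. 0.05/18 is
    0.002778.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return float(f"{alpha / m:.4g}")
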