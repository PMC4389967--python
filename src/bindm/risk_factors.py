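"""Case-control risk-factor analysis: crude odds ratios with Woolf intervals.

Exposures (sepsis, menthol application, G6PD status, ...) are compared
between infants with ABE (cases) and without (controls).  For a 2x2 table

    =============  ======  ========
    ..             cases   controls
    exposed        a       c
    referent       b       d
    =============  ======  ========

the crude odds ratio is ``OR = (a*d) / (b*c)`` and the Woolf (logit) 95% CI
is ``exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d))``.  For a saturated
single-factor unconditional logistic model the fitted level odds ratios
coincide with these cross-product ratios, so the closed form is used
throughout.

Zero cells receive no continuity correction; they produce explicit flags
instead (``zero_point``, ``infinite_upper``, ``incalculable``), matching how
degenerate rows are conventionally printed ("0.000 (incalculable)",
upper bound ">999" / "infinity").

A multi-level exposure is handled by :func:`categorical_ors`: each level is
compared against the declared referent level in its own 2x2.  For the joint
menthol x G6PD exposure the referent is the "grand referent" — infants who
were neither menthol-exposed nor enzyme deficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TwoByTwo",
    "ORFlag",
    "OddsRatioResult",
    "CategoricalExposureTable",
    "MeanComparison",
    "CaseControlAnalysis",
    "crude_or",
    "woolf_ci",
    "categorical_ors",
    "compare_means",
    "DISPLAY_CAP",
]

#: upper CI bounds beyond this render as ">999"
DISPLAY_CAP = 999.0


class ORFlag(str, Enum):
    OK = "ok"
    INFINITE_UPPER = "infinite_upper"
    ZERO_POINT = "zero_point"
    INCALCULABLE = "incalculable"


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: a, b = cases; c, d = controls."""

    cases_exposed: int
    cases_referent: int
    controls_exposed: int
    controls_referent: int

    def __post_init__(self) -> None:
        cells = self.cells
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.cases_exposed, self.cases_referent,
                self.controls_exposed, self.controls_referent)


@dataclass(frozen=True)
class OddsRatioResult:
    """Crude odds ratio vs the referent, with Woolf CI and degeneracy flag."""

    point: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    flag: ORFlag
    label: str = ""
    display_cap: float = DISPLAY_CAP

    def format(self) -> str:
        """Render like the conventional case-control table."""
        if self.flag is ORFlag.INCALCULABLE:
            return "0.000 (incalculable)"
        if self.flag is ORFlag.ZERO_POINT:
            return "0.000 (0.000, incalculable)"
        point = "infinity" if self.point == math.inf else f"{self.point:.3f}"
        if self.ci_low is None:
            return point
        hi = (">%g" % self.display_cap
              if self.ci_high is None or self.ci_high > self.display_cap
              else f"{self.ci_high:.3f}")
        lo = f"{self.ci_low:.3f}" if self.ci_low is not None else "incalculable"
        return f"{point} ({lo}, {hi})"


def _flag_for(t: TwoByTwo) -> ORFlag:
    a, b, c, d = t.cells
    if a == 0 and c == 0:
        return ORFlag.INCALCULABLE  # exposed level never observed
    if b * c == 0:
        return ORFlag.INFINITE_UPPER
    if a * d == 0:
        return ORFlag.ZERO_POINT
    return ORFlag.OK


def crude_or(t: TwoByTwo, label: str = "") -> OddsRatioResult:
    """Cross-product odds ratio (point estimate only, no CI)."""
    a, b, c, d = t.cells
    flag = _flag_for(t)
    if flag is ORFlag.INCALCULABLE:
        point = None
    elif flag is ORFlag.INFINITE_UPPER:
        point = math.inf if a * d > 0 else None
    elif flag is ORFlag.ZERO_POINT:
        point = 0.0
    else:
        point = (a * d) / (b * c)
    return OddsRatioResult(point=point, ci_low=None, ci_high=None,
                           flag=flag, label=label)


def woolf_ci(t: TwoByTwo, z: float = 1.96, label: str = "") -> OddsRatioResult:
    """Odds ratio with the Woolf logit confidence interval.

    Finite bounds require all four cells > 0; zero cells propagate the
    degeneracy flags of :func:`crude_or` (no continuity correction).
    """
    base = crude_or(t, label=label)
    a, b, c, d = t.cells
    if base.flag is not ORFlag.OK:
        return base
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(base.point)
    return OddsRatioResult(
        point=base.point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        flag=ORFlag.OK,
        label=label,
    )


@dataclass(frozen=True)
class CategoricalExposureTable:
    """Case/control counts per exposure level, with a declared referent."""

    factor: str
    levels: tuple[tuple[str, int, int], ...]  # (label, cases, controls)
    referent_index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.referent_index < len(self.levels):
            raise ValueError("referent_index out of range")
        object.__setattr__(self, "levels", tuple(tuple(lv) for lv in self.levels))

    @property
    def referent(self) -> tuple[str, int, int]:
        return self.levels[self.referent_index]

    @property
    def total_cases(self) -> int:
        return sum(lv[1] for lv in self.levels)

    @property
    def total_controls(self) -> int:
        return sum(lv[2] for lv in self.levels)


def categorical_ors(tab: CategoricalExposureTable,
                    z: float = 1.96) -> list[OddsRatioResult]:
    """Odds ratio of every non-referent level against the referent level.

    Each level forms its own 2x2 with the referent; the referent itself is
    reported as 1.000 with the label annotated "[Referent]".
    """
    ref_label, ref_cases, ref_controls = tab.referent
    results: list[OddsRatioResult] = []
    for i, (label, cases, controls) in enumerate(tab.levels):
        if i == tab.referent_index:
            results.append(OddsRatioResult(
                point=1.0, ci_low=None, ci_high=None, flag=ORFlag.OK,
                label=f"{label} [Referent]",
            ))
            continue
        t = TwoByTwo(cases, ref_cases, controls, ref_controls)
        results.append(woolf_ci(t, z=z, label=label))
    return results


@dataclass(frozen=True)
class MeanComparison:
    """Two-sample comparison of a continuous variable between cases and controls.

    Both the pooled-variance (Student) and unequal-variance (Welch) t tests
    are computed; the pooled variant is the conventional default shown in
    summaries.
    """

    mean_cases: float
    mean_controls: float
    n_cases: int
    n_controls: int
    t_pooled: float
    p_pooled: float
    t_welch: float
    p_welch: float

    def summary(self) -> str:
        return (
            f"cases:    n={self.n_cases:4d}  mean={self.mean_cases:.2f}\n"
            f"controls: n={self.n_controls:4d}  mean={self.mean_controls:.2f}\n"
            f"pooled t = {self.t_pooled:.3f}  (p = {self.p_pooled:.4g})\n"
            f"Welch  t = {self.t_welch:.3f}  (p = {self.p_welch:.4g})"
        )


def compare_means(x: Sequence[float], y: Sequence[float]) -> MeanComparison:
    """Compare group means of cases ``x`` versus controls ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t_p, p_p = stats.ttest_ind(x, y, equal_var=True)
    t_w, p_w = stats.ttest_ind(x, y, equal_var=False)
    return MeanComparison(
        mean_cases=float(x.mean()), mean_controls=float(y.mean()),
        n_cases=int(x.size), n_controls=int(y.size),
        t_pooled=float(t_p), p_pooled=float(p_p),
        t_welch=float(t_w), p_welch=float(p_w),
    )


class CaseControlAnalysis:
    """Model-style wrapper for one categorical exposure table.

    >>> tab = CategoricalExposureTable("sepsis", (("no", 4, 67), ("yes", 12, 24)))
    >>> res = CaseControlAnalysis(tab).fit()
    >>> round(res[1].point, 3)
    8.375
    """

    def __init__(self, table: CategoricalExposureTable):
        self.table = table

    def fit(self, z: float = 1.96) -> list[OddsRatioResult]:
        return categorical_ors(self.table, z=z)
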