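"""Diagnostic accuracy of the BIND-M total score against the ABE diagnosis.

An infant tests positive at cutoff ``c`` when the total score is >= c.  The
consultant's clinical call of acute bilirubin encephalopathy is the reference
standard.  For each cutoff the confusion counts (TP, FN, FP, TN) and the four
accuracy metrics are reported:

    sensitivity = 100 * TP / (TP + FN)     specificity = 100 * TN / (FP + TN)
    PPV         = 100 * TP / (TP + FP)     NPV         = 100 * TN / (TN + FN)

A metric whose denominator is zero (e.g. NPV at cutoff 0, where nobody tests
negative) is *undefined* and rendered "N/A"; it is never coerced to 0 or 100.
Values are kept at full precision internally and displayed to one decimal
(round-half-even).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .rubric import MAX_TOTAL

__all__ = [
    "ThresholdPerformance",
    "PerformanceSweep",
    "ThresholdAnalysis",
    "confusion_at_threshold",
    "sweep_thresholds",
]


def _ratio(num: int, den: int) -> Optional[float]:
    if den == 0:
        return None
    return 100.0 * num / den


@dataclass(frozen=True)
class ThresholdPerformance:
    """Confusion counts and accuracy metrics at one score cutoff."""

    cutoff: int
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _ratio(self.tn, self.fp + self.tn)

    @property
    def ppv(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fn)

    def metrics(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class PerformanceSweep:
    """One :class:`ThresholdPerformance` row per cutoff 0..12."""

    rows: tuple[ThresholdPerformance, ...]

    @property
    def n(self) -> int:
        return self.rows[0].n

    @property
    def n_positive(self) -> int:
        return self.rows[0].tp + self.rows[0].fn

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n

    def row(self, cutoff: int) -> ThresholdPerformance:
        for r in self.rows:
            if r.cutoff == cutoff:
                return r
        raise KeyError(f"no row for cutoff {cutoff}")

    def summary(self) -> str:
        from .io import render_report  # late import: io renders, diagnostics computes

        return render_report(self, layout="table3")


def confusion_at_threshold(scores: Sequence[int], truth: Sequence[bool],
                           cutoff: int) -> ThresholdPerformance:
    """Confusion counts for test-positive := score >= cutoff."""
    scores = np.asarray(scores)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be 1-D of equal length")
    if scores.size == 0:
        raise ValueError("no observations")
    if scores.min() < 0 or scores.max() > MAX_TOTAL:
        raise ValueError(f"scores must lie in [0, {MAX_TOTAL}]")
    pos = scores >= cutoff
    return ThresholdPerformance(
        cutoff=cutoff,
        tp=int((pos & truth).sum()),
        fn=int((~pos & truth).sum()),
        fp=int((pos & ~truth).sum()),
        tn=int((~pos & ~truth).sum()),
    )


def sweep_thresholds(scores: Sequence[int], truth: Sequence[bool],
                     cutoffs: Iterable[int] = range(MAX_TOTAL + 1)) -> PerformanceSweep:
    """Confusion counts and metrics at every cutoff (default >=0 .. >=12)."""
    rows = tuple(confusion_at_threshold(scores, truth, c) for c in cutoffs)
    if not rows:
        raise ValueError("no cutoffs requested")
    return PerformanceSweep(rows)


class ThresholdAnalysis:
    """Model-style wrapper: scores + reference diagnoses in, sweep out.

    >>> res = ThresholdAnalysis([0, 4, 9], [False, True, True]).fit()
    >>> res.row(3).tp
    2
    """

    def __init__(self, scores: Sequence[int], truth: Sequence[bool]):
        self.scores = list(scores)
        self.truth = list(truth)

    def fit(self, cutoffs: Iterable[int] = range(MAX_TOTAL + 1)) -> PerformanceSweep:
        return sweep_thresholds(self.scores, self.truth, cutoffs)
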