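"""The BIND-M scoring rubric.

The modified bilirubin-induced neurologic dysfunction score (BIND-M) grades
acute bilirubin encephalopathy (ABE) in jaundiced neonates from four bedside
findings: mental status, muscle tone and cry are each scored 0 (normal) to 3
(severe), while paralysis of upward gaze — an all-or-nothing classic sign —
scores either 0 or 3.  The total therefore ranges 0–12.

Two framings of the total coexist and both are kept:

* the a-priori severity bands (0 none, 1–4 mild, 5–6 moderate, ≥7 severe),
  intended to grade reversibility of the encephalopathy, and
* the empirical screening threshold (total ≥ 3 predicts a clinical
  diagnosis of ABE), which is the operating point the evaluation modules
  (:mod:`bindm.diagnostics`) characterise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "DomainError",
    "Severity",
    "Rater",
    "SubscoreAssessment",
    "ExamRecord",
    "SUBSCALES",
    "GAZE_LEVELS",
    "MAX_TOTAL",
    "DEFAULT_ABE_THRESHOLD",
    "total_score",
    "classify_severity",
    "predict_abe",
    "any_subscale_at_least",
    "score_without_gaze",
]

#: the four clinical domains, in canonical column order
SUBSCALES = ("mental_status", "muscle_tone", "cry", "gaze")

#: graded sub-scales take any of these levels
ORDINAL_LEVELS = (0, 1, 2, 3)

#: upward-gaze paralysis is all-or-nothing: normal (0) or present (3)
GAZE_LEVELS = (0, 3)

MAX_TOTAL = 12

#: empirical screening cutoff: total >= 3 predicts clinical ABE
DEFAULT_ABE_THRESHOLD = 3


class DomainError(ValueError):
    """An input violates the rubric's domain (bad level, bad range)."""


class Severity(str, Enum):
    """A-priori severity bands of the total score."""

    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Rater(str, Enum):
    RESIDENT = "resident"
    CONSULTANT = "consultant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SubscoreAssessment:
    """One rater's four BIND-M sub-scores for one infant.

    ``mental_status``, ``muscle_tone`` and ``cry`` are ordinal 0–3;
    ``gaze`` is 0 or 3.
    """

    mental_status: int
    muscle_tone: int
    cry: int
    gaze: int

    def __post_init__(self) -> None:
        for name in ("mental_status", "muscle_tone", "cry"):
            level = getattr(self, name)
            if level not in ORDINAL_LEVELS:
                raise DomainError(
                    f"{name} must be one of {ORDINAL_LEVELS}, got {level!r}"
                )
        if self.gaze not in GAZE_LEVELS:
            raise DomainError(
                f"gaze must be one of {GAZE_LEVELS} (all-or-nothing sign), "
                f"got {self.gaze!r}"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.mental_status, self.muscle_tone, self.cry, self.gaze)


@dataclass(frozen=True)
class ExamRecord:
    """One rater's examination of one infant.

    The consultant's clinical ABE call is the study's reference standard, so
    ``abe_diagnosis`` may only be present on consultant records.
    """

    infant_id: str
    rater: Rater
    assessment: SubscoreAssessment
    abe_diagnosis: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.abe_diagnosis is not None and self.rater is not Rater.CONSULTANT:
            raise DomainError(
                "abe_diagnosis is the consultant reference standard and may "
                f"only appear on consultant records (infant {self.infant_id})"
            )


def total_score(assessment: SubscoreAssessment) -> int:
    """Total BIND-M score: plain sum of the four sub-scores, in [0, 12]."""
    return sum(assessment.as_tuple())


def classify_severity(total: int) -> Severity:
    """Map a total score to its a-priori severity band.

    0 is no ABE; 1–4 mild (generally reversible with prompt treatment);
    5–6 moderate (possibly reversible with urgent bilirubin reduction);
    7 and above severe/very severe (probably irreversible injury).
    """
    if not 0 <= total <= MAX_TOTAL:
        raise DomainError(f"total score must be in [0, {MAX_TOTAL}], got {total!r}")
    if total == 0:
        return Severity.NONE
    if total <= 4:
        return Severity.MILD
    if total <= 6:
        return Severity.MODERATE
    return Severity.SEVERE


def predict_abe(total: int, threshold: int = DEFAULT_ABE_THRESHOLD) -> bool:
    """True when the total score meets the ABE screening threshold.

    The default cutoff of 3 is the empirically supported operating point;
    any cutoff in [0, 12] may be supplied to explore the trade-off (see
    :func:`bindm.diagnostics.sweep_thresholds`).
    """
    if not 0 <= total <= MAX_TOTAL:
        raise DomainError(f"total score must be in [0, {MAX_TOTAL}], got {total!r}")
    if not 0 <= threshold <= MAX_TOTAL:
        raise DomainError(f"threshold must be in [0, {MAX_TOTAL}], got {threshold!r}")
    return total >= threshold


def any_subscale_at_least(assessment: SubscoreAssessment, level: int) -> bool:
    """True when at least one sub-score reaches ``level``.

    ``any_subscale_at_least(a, 2)`` is the "moderate or severe finding on at
    least one subscale" flag used as an alternative single-criterion screen.
    """
    if level not in ORDINAL_LEVELS:
        raise DomainError(f"level must be in {ORDINAL_LEVELS}, got {level!r}")
    return max(assessment.as_tuple()) >= level


def score_without_gaze(assessment: SubscoreAssessment) -> int:
    """Total score with the eye-finding points removed, in [0, 9].

    With gaze excluded BIND-M reduces to a 0–9 scale over the three graded
    sub-scores; this checks how much the screen leans on the eye finding.
    """
    return total_score(assessment) - assessment.gaze
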