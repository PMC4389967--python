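"""Inter-rater agreement between resident and consultant BIND-M ratings.

Agreement on an ordinal scale is summarised by Cohen's kappa computed on the
square resident-by-consultant contingency table.  Two weighting schemes are
supported:

* *identity* weights (credit only for exact agreement) — the simple kappa;
* *Cicchetti–Allen linear* weights ``w_ij = 1 - |c_i - c_j| / (c_max - c_min)``,
  which give partial credit for near-diagonal disagreement and are the
  classical default for ordinal clinical scales.

With cell proportions ``p_ij`` and marginals ``p_i.``, ``p_.j``::

    p_o = sum_ij w_ij p_ij          (observed weighted agreement)
    p_e = sum_ij w_ij p_i. p_.j     (chance-expected weighted agreement)
    kappa = (p_o - p_e) / (1 - p_e)

Standard errors use the Fleiss–Cohen–Everitt asymptotic (non-null) variance
of the weighted kappa, and confidence intervals are Wald intervals
``kappa ± z * se`` clipped to kappa's range [-1, 1].

The model-style entry point is :class:`InterRaterAgreement`; the functional
entry points :func:`weighted_kappa` and :func:`simple_kappa` are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .rubric import SUBSCALES, GAZE_LEVELS, MAX_TOTAL, ExamRecord, Rater, total_score

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "InterRaterAgreement",
    "PairingError",
    "UndefinedKappaError",
    "ca_weight",
    "linear_weight_matrix",
    "identity_weight_matrix",
    "weighted_kappa",
    "simple_kappa",
    "cross_tabulate",
    "default_categories",
]

WEIGHTING_LINEAR = "cicchetti_allen_linear"
WEIGHTING_IDENTITY = "identity"


class PairingError(ValueError):
    """Exam records cannot be paired one resident + one consultant per infant."""


class UndefinedKappaError(ZeroDivisionError):
    """Kappa is undefined: chance-expected agreement equals 1."""


@dataclass(frozen=True)
class ContingencyTable:
    """Square table of paired ordinal ratings.

    Rows index the first rater (residents), columns the second rater
    (consultants).  ``categories`` holds the ordered numeric level values the
    axes share, e.g. ``(0, 1, 2, 3)`` for a graded sub-score or ``(0, 3)``
    for the gaze sign; the numeric values (not their ranks) drive the linear
    weights.
    """

    categories: tuple[int, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))
        k = len(self.categories)
        if k < 2:
            raise ValueError("need at least 2 categories")
        if any(b <= a for a, b in zip(self.categories, self.categories[1:])):
            raise ValueError(f"categories must be strictly increasing: {self.categories}")
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table is empty (n = 0)")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.categories, self.counts.T.copy())


@dataclass(frozen=True)
class KappaResult:
    """A kappa estimate with its asymptotic uncertainty.

    ``se`` is the Fleiss–Cohen–Everitt asymptotic standard error and the CI
    is the symmetric Wald interval ``estimate ± z_crit * se`` clipped to
    [-1, 1].
    """

    estimate: float
    weighting: str
    p_o: float
    p_e: float
    se: float
    ci_low: float
    ci_high: float
    z_crit: float = 1.96

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def summary(self) -> str:
        label = "Weighted Kappa" if self.weighting == WEIGHTING_LINEAR else "Simple Kappa"
        lines = [
            f"{label} = {self.estimate:.4f} "
            f"(95% CI: {self.ci_low:.4f}, {self.ci_high:.4f})",
            f"  observed agreement p_o = {self.p_o:.4f}",
            f"  expected agreement p_e = {self.p_e:.4f}",
            f"  asymptotic SE = {self.se:.4f}   (weights: {self.weighting})",
        ]
        return "\n".join(lines)


def ca_weight(ci: float, cj: float, cmin: float, cmax: float) -> float:
    """Cicchetti–Allen linear agreement weight for category values ci, cj.

    ``1 - |ci - cj| / (cmax - cmin)``: 1 on the diagonal, 0 at the extreme
    disagreement, linear in between.
    """
    if cmax <= cmin:
        raise ValueError("degenerate category set: cmax must exceed cmin")
    return 1.0 - abs(ci - cj) / (cmax - cmin)


def linear_weight_matrix(categories: Sequence[float]) -> np.ndarray:
    c = np.asarray(categories, dtype=float)
    return 1.0 - np.abs(c[:, None] - c[None, :]) / (c.max() - c.min())


def identity_weight_matrix(categories: Sequence[float]) -> np.ndarray:
    return np.eye(len(categories))


def _kappa_from_weights(table: ContingencyTable, w: np.ndarray, weighting: str,
                        z_crit: float) -> KappaResult:
    p = table.proportions
    n = table.n
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(p_row, p_col)).sum())
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "expected agreement is 1 (all mass in one marginal category); "
            "kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt asymptotic (non-null) variance of weighted kappa
    wbar_row = w @ p_col          # row-wise expected weight, given rater A level
    wbar_col = w.T @ p_row        # column-wise expected weight, given rater B level
    core = (w * (1.0 - p_e) - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - p_o)) ** 2
    var = ((p * core).sum() - (p_o * p_e - 2.0 * p_e + p_o) ** 2) / (n * (1.0 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))

    ci_low = max(kappa - z_crit * se, -1.0)
    ci_high = min(kappa + z_crit * se, 1.0)
    return KappaResult(
        estimate=float(kappa), weighting=weighting, p_o=p_o, p_e=p_e,
        se=se, ci_low=ci_low, ci_high=ci_high, z_crit=z_crit,
    )


def weighted_kappa(table: ContingencyTable,
                   weighting: str = WEIGHTING_LINEAR,
                   z_crit: float = 1.96) -> KappaResult:
    """Kappa on a contingency table under the requested weighting scheme."""
    if weighting == WEIGHTING_LINEAR:
        w = linear_weight_matrix(table.categories)
    elif weighting == WEIGHTING_IDENTITY:
        w = identity_weight_matrix(table.categories)
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    return _kappa_from_weights(table, w, weighting, z_crit)


def simple_kappa(table: ContingencyTable, z_crit: float = 1.96) -> KappaResult:
    """Cohen's simple (identity-weighted) kappa."""
    return weighted_kappa(table, weighting=WEIGHTING_IDENTITY, z_crit=z_crit)


class InterRaterAgreement:
    """Agreement model for one paired-rating contingency table.

    Mirrors the model/results idiom: construct from a table (or from paired
    exam records via :meth:`from_records`), then ``fit()`` returns a
    :class:`KappaResult`.

    >>> t = ContingencyTable((0, 3), [[301, 12], [6, 14]])
    >>> res = InterRaterAgreement(t).fit(weighting="identity")
    >>> round(res.estimate, 4)
    0.5802
    """

    def __init__(self, table: ContingencyTable):
        self.table = table

    @classmethod
    def from_records(cls, records: Iterable[ExamRecord], field: str,
                     categories: Optional[Sequence[int]] = None) -> "InterRaterAgreement":
        return cls(cross_tabulate(records, field, categories=categories))

    def fit(self, weighting: str = WEIGHTING_LINEAR, z_crit: float = 1.96) -> KappaResult:
        return weighted_kappa(self.table, weighting=weighting, z_crit=z_crit)


def default_categories(field: str) -> tuple[int, ...]:
    """Declared category space of a rating field (kept even when unobserved)."""
    if field == "gaze":
        return GAZE_LEVELS
    if field == "total":
        return tuple(range(MAX_TOTAL + 1))
    if field in SUBSCALES:
        return (0, 1, 2, 3)
    raise ValueError(f"unknown rating field {field!r}")


def _field_value(record: ExamRecord, field: str) -> int:
    if field == "total":
        return total_score(record.assessment)
    return getattr(record.assessment, field)


def cross_tabulate(records: Iterable[ExamRecord], field: str,
                   categories: Optional[Sequence[int]] = None) -> ContingencyTable:
    """Cross-tabulate resident-vs-consultant ratings of one field.

    Every infant must contribute exactly one resident and one consultant
    record.  The table spans the field's full declared category set even when
    some levels were never used, so kappa is computed on the rubric's
    category space.
    """
    if categories is None:
        categories = default_categories(field)
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}

    by_infant: dict[str, dict[Rater, ExamRecord]] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        slot = by_infant.setdefault(rec.infant_id, {})
        if rec.rater in slot:
            raise PairingError(
                f"infant {rec.infant_id!r} has more than one {rec.rater.value} record"
            )
        slot[rec.rater] = rec
    if n_records == 0:
        raise PairingError("no exam records supplied")

    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for infant_id, pair in by_infant.items():
        if Rater.RESIDENT not in pair or Rater.CONSULTANT not in pair:
            raise PairingError(
                f"infant {infant_id!r} is missing a "
                f"{'resident' if Rater.RESIDENT not in pair else 'consultant'} record"
            )
        r_val = _field_value(pair[Rater.RESIDENT], field)
        c_val = _field_value(pair[Rater.CONSULTANT], field)
        try:
            counts[index[r_val], index[c_val]] += 1
        except KeyError as exc:
            raise ValueError(
                f"rating {exc.args[0]!r} for infant {infant_id!r} is outside "
                f"the declared categories {categories}"
            ) from None
    return ContingencyTable(categories, counts)
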