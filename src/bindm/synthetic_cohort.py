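"""Synthetic per-infant exam cohorts with the study's statistical structure.

No per-infant data are deposited for the BIND-M evaluation; this module
generates cohorts that emulate its published structure so every pipeline
stage (scoring, agreement, threshold sweep, odds ratios) can be exercised
end to end:

* a latent ABE status per infant (default prevalence 53/333);
* consultant sub-scores drawn from status-conditional categorical profiles.
  ABE infants are a mixture of a dominant *severe* profile and a small
  *mild* component that scores low on every scale, so that roughly 90% of
  ABE infants reach total >= 3 while roughly 98% of unaffected infants stay
  below it — the screening operating point the score was reported to have;
* resident ratings derived from the consultant ratings through an ordinal
  confusion kernel: stay with probability ``p_stay``, otherwise move to an
  adjacent level (split evenly between neighbours, clipped at the scale
  ends).  Gaze, being binary, gets a simple flip probability.  The defaults
  are calibrated so the resident-vs-consultant weighted kappa is ~0.80 on
  the graded scales and ~0.58 on gaze;
* categorical risk factors sampled so that each level's exposure-ABE
  association has a configured odds ratio (sepsis OR 8.375; a joint
  menthol x G6PD grid whose referent is the doubly unexposed group, with
  the menthol-exposed/G6PD-deficient cell at OR 74);
* a positive continuous peak-bilirubin variable (cases ~30.7 mg/dL,
  controls ~15.65 mg/dL, truncated normal).

All randomness flows through one :class:`numpy.random.Generator` seeded from
the config, so a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rubric import (
    SUBSCALES,
    GAZE_LEVELS,
    ExamRecord,
    Rater,
    SubscoreAssessment,
    total_score,
)
from .agreement import ContingencyTable, weighted_kappa, default_categories

__all__ = [
    "ConfigError",
    "CalibrationError",
    "RaterNoise",
    "RiskFactorSpec",
    "BilirubinSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "noise_kernel",
    "expected_kappa",
    "calibrate_noise",
    "DEFAULT_PROFILES",
    "DEFAULT_ABE_MILD_FRACTION",
    "DEFAULT_SEPSIS",
    "DEFAULT_MENTHOL_G6PD",
]


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


class CalibrationError(RuntimeError):
    """The requested agreement level cannot be reached by the noise model."""


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: status-conditional sub-score profiles (probabilities over levels).
#: Calibration targets: the mixture marginals approximate the consultant
#: column totals of the published sub-score tables, and the implied
#: operating point at cutoff 3 is ~90% sensitivity / ~98.5% specificity.
DEFAULT_PROFILES: Mapping[str, Mapping[str, tuple[float, ...]]] = {
    "control": {
        "mental_status": (0.898, 0.079, 0.0220, 0.0010),
        "muscle_tone": (0.914, 0.058, 0.0250, 0.0030),
        "cry": (0.968, 0.018, 0.0095, 0.0045),
        "gaze": (1.0, 0.0),
    },
    "abe_mild": {
        "mental_status": (0.50, 0.45, 0.05, 0.0),
        "muscle_tone": (0.45, 0.50, 0.05, 0.0),
        "cry": (0.65, 0.30, 0.05, 0.0),
        "gaze": (1.0, 0.0),
    },
    "abe_severe": {
        "mental_status": (0.08, 0.09, 0.62, 0.21),
        "muscle_tone": (0.07, 0.08, 0.43, 0.42),
        "cry": (0.19, 0.07, 0.19, 0.55),
        "gaze": (0.51, 0.49),
    },
}

#: fraction of ABE infants following the low-scoring mild profile
DEFAULT_ABE_MILD_FRACTION = 0.105

#: stay probability giving expected weighted kappa 0.80 on mental status
DEFAULT_P_STAY = 0.8588

#: gaze flip probability giving expected simple kappa 0.58
DEFAULT_GAZE_FLIP = 0.0791


@dataclass(frozen=True)
class RaterNoise:
    """Resident-rating noise relative to the consultant rating."""

    p_stay: float = DEFAULT_P_STAY
    gaze_flip: float = DEFAULT_GAZE_FLIP

    def __post_init__(self) -> None:
        for name in ("p_stay", "gaze_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"rater_noise.{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class RiskFactorSpec:
    """A categorical exposure with configured per-level odds ratios.

    ``control_probs`` is the exposure distribution among controls;
    the case distribution is derived by inverting the odds-ratio relation:
    ``P(level | case) ∝ P(level | control) * OR(level)``, which makes each
    level's crude OR against the referent exactly the configured value (in
    expectation).  ``columns`` names the output column(s); each level is a
    tuple of values for those columns (a joint factor spans two columns).
    """

    name: str
    columns: tuple[str, ...]
    levels: tuple[tuple[str, ...], ...]
    control_probs: tuple[float, ...]
    odds_ratios: tuple[float, ...]
    referent_index: int = 0

    def __post_init__(self) -> None:
        k = len(self.levels)
        if not (len(self.control_probs) == len(self.odds_ratios) == k):
            raise ConfigError(f"risk factor {self.name!r}: level/prob/OR lengths differ")
        if any(p < 0 for p in self.control_probs) or abs(sum(self.control_probs) - 1) > 1e-9:
            raise ConfigError(f"risk factor {self.name!r}: control_probs must sum to 1")
        if any(o < 0 for o in self.odds_ratios):
            raise ConfigError(f"risk factor {self.name!r}: odds ratios must be >= 0")
        if self.odds_ratios[self.referent_index] != 1.0:
            raise ConfigError(f"risk factor {self.name!r}: referent OR must be 1.0")

    @property
    def case_probs(self) -> tuple[float, ...]:
        raw = [p * o for p, o in zip(self.control_probs, self.odds_ratios)]
        s = sum(raw)
        if s <= 0:
            raise ConfigError(f"risk factor {self.name!r}: degenerate case distribution")
        return tuple(r / s for r in raw)


def _sepsis_default() -> RiskFactorSpec:
    # exposure among controls 24/91; configured OR 8.375
    return RiskFactorSpec(
        name="sepsis",
        columns=("sepsis",),
        levels=(("0",), ("1",)),
        control_probs=(67 / 91, 24 / 91),
        odds_ratios=(1.0, 8.375),
    )


def _menthol_g6pd_default() -> RiskFactorSpec:
    # joint menthol x G6PD grid; control distribution from the published
    # control margin (n=170), per-cell crude odds ratios vs the grand
    # referent (menthol-unexposed, G6PD-normal).
    levels = (
        ("unexposed", "normal"),     # grand referent
        ("unexposed", "unknown"),
        ("unexposed", "deficient"),
        ("unknown", "normal"),
        ("unknown", "unknown"),
        ("unknown", "deficient"),
        ("exposed", "normal"),       # never observed
        ("exposed", "unknown"),
        ("exposed", "deficient"),
    )
    controls = (37, 63, 17, 10, 25, 6, 0, 10, 2)
    cases = (1, 10, 3, 1, 1, 1, 0, 7, 4)
    n_ctl = sum(controls)
    ors = tuple(
        1.0 if i == 0 else
        (0.0 if controls[i] == 0 else (cases[i] * controls[0]) / (cases[0] * controls[i]))
        for i in range(len(levels))
    )
    return RiskFactorSpec(
        name="menthol_g6pd",
        columns=("menthol", "g6pd"),
        levels=levels,
        control_probs=tuple(c / n_ctl for c in controls),
        odds_ratios=ors,
    )


DEFAULT_SEPSIS = _sepsis_default()
DEFAULT_MENTHOL_G6PD = _menthol_g6pd_default()


@dataclass(frozen=True)
class BilirubinSpec:
    """Peak serum bilirubin (mg/dL): normal truncated at 0, per group."""

    case_mean: float = 30.71
    case_sd: float = 8.0
    control_mean: float = 15.65
    control_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.case_sd <= 0 or self.control_sd <= 0:
            raise ConfigError("bilirubin SDs must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort (defaults = study conditions)."""

    n: int = 333
    abe_prevalence: float = 53 / 333
    subscore_profiles: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=lambda: DEFAULT_PROFILES)
    abe_mild_fraction: float = DEFAULT_ABE_MILD_FRACTION
    rater_noise: RaterNoise = field(default_factory=RaterNoise)
    risk_factors: tuple[RiskFactorSpec, ...] = field(
        default_factory=lambda: (DEFAULT_SEPSIS, DEFAULT_MENTHOL_G6PD))
    bilirubin: BilirubinSpec = field(default_factory=BilirubinSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.abe_prevalence <= 1.0:
            raise ConfigError(f"abe_prevalence must be in [0, 1], got {self.abe_prevalence}")
        if not 0.0 <= self.abe_mild_fraction <= 1.0:
            raise ConfigError(f"abe_mild_fraction must be in [0, 1]")
        for status in ("control", "abe_mild", "abe_severe"):
            if status not in self.subscore_profiles:
                raise ConfigError(f"subscore_profiles missing status {status!r}")
            prof = self.subscore_profiles[status]
            for scale in SUBSCALES:
                if scale not in prof:
                    raise ConfigError(
                        f"subscore_profiles[{status!r}] missing scale {scale!r}")
                p = prof[scale]
                want = 2 if scale == "gaze" else 4
                if len(p) != want:
                    raise ConfigError(
                        f"subscore_profiles[{status!r}][{scale!r}] needs {want} "
                        f"probabilities, got {len(p)}")
                if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"subscore_profiles[{status!r}][{scale!r}] must be a "
                        f"probability vector summing to 1")


def noise_kernel(p_stay: float, n_levels: int) -> np.ndarray:
    """Column-stochastic ordinal confusion kernel T[i, j] = P(rated i | true j).

    Stay with probability ``p_stay``; otherwise move to an adjacent level,
    splitting the spillover evenly between the neighbours (all of it to the
    single neighbour at the scale ends).  ``n_levels == 2`` degenerates to a
    plain flip matrix.
    """
    T = np.zeros((n_levels, n_levels))
    for j in range(n_levels):
        T[j, j] = p_stay
        neighbours = [i for i in (j - 1, j + 1) if 0 <= i < n_levels]
        for i in neighbours:
            T[i, j] += (1.0 - p_stay) / len(neighbours)
    return T


def _status_labels(abe: np.ndarray, mild: np.ndarray) -> np.ndarray:
    out = np.where(abe, np.where(mild, "abe_mild", "abe_severe"), "control")
    return out


def _draw_categorical(u: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Inverse-CDF draw so one uniform per observation fixes the stream."""
    cum = np.cumsum(probs)
    cum[-1] = 1.0  # guard rounding
    return np.searchsorted(cum, u, side="right")


class SyntheticCohort:
    """A generated cohort: paired exam records plus risk-factor covariates."""

    def __init__(self, frame: pd.DataFrame, config: CohortConfig):
        self.frame = frame
        self.config = config

    @property
    def n(self) -> int:
        return self.frame["infant_id"].nunique()

    @property
    def truth(self) -> pd.Series:
        """Latent ABE status, one value per infant (indexed by infant_id)."""
        per = self.frame.drop_duplicates("infant_id").set_index("infant_id")
        return per["abe_truth"].astype(bool)

    def records(self) -> list[ExamRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            rater = Rater(row.rater)
            out.append(ExamRecord(
                infant_id=row.infant_id,
                rater=rater,
                assessment=SubscoreAssessment(
                    row.mental_status, row.muscle_tone, row.cry, row.gaze),
                abe_diagnosis=(bool(row.abe_diagnosis)
                               if rater is Rater.CONSULTANT else None),
            ))
        return out

    def consultant_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(total scores, latent ABE truth), consultant ratings, per infant."""
        cons = self.frame[self.frame["rater"] == "consultant"]
        totals = (cons[list(SUBSCALES)].sum(axis=1)).to_numpy()
        return totals, cons["abe_truth"].to_numpy(dtype=bool)

    def risk_factor_table(self, factor: RiskFactorSpec):
        """Case/control level counts of one configured factor."""
        from .risk_factors import CategoricalExposureTable

        cons = self.frame[self.frame["rater"] == "consultant"]
        truth = cons["abe_truth"].to_numpy(dtype=bool)
        levels = []
        for level in factor.levels:
            mask = np.ones(len(cons), dtype=bool)
            for col, val in zip(factor.columns, level):
                mask &= (cons[col] == val).to_numpy()
            levels.append(("/".join(level), int((mask & truth).sum()),
                           int((mask & ~truth).sum())))
        return CategoricalExposureTable(
            factor=factor.name, levels=tuple(levels),
            referent_index=factor.referent_index)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def generate_cohort(config: Optional[CohortConfig] = None,
                    seed: Optional[int] = None) -> SyntheticCohort:
    """Generate one cohort; deterministic for a fixed config (and seed)."""
    cfg = config if config is not None else CohortConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    abe = rng.random(n) < cfg.abe_prevalence
    mild = rng.random(n) < cfg.abe_mild_fraction
    status = _status_labels(abe, mild)

    # consultant sub-scores (level indices), then resident via the kernel
    consultant: dict[str, np.ndarray] = {}
    resident: dict[str, np.ndarray] = {}
    for scale in SUBSCALES:
        values = np.array(GAZE_LEVELS if scale == "gaze" else (0, 1, 2, 3))
        idx = np.zeros(n, dtype=np.int64)
        u = rng.random(n)
        for st in ("control", "abe_mild", "abe_severe"):
            mask = status == st
            if mask.any():
                idx[mask] = _draw_categorical(
                    u[mask], cfg.subscore_profiles[st][scale])
        consultant[scale] = values[idx]

        p_stay = (1.0 - cfg.rater_noise.gaze_flip if scale == "gaze"
                  else cfg.rater_noise.p_stay)
        T = noise_kernel(p_stay, len(values))
        u2 = rng.random(n)
        res_idx = np.zeros(n, dtype=np.int64)
        for j in range(len(values)):
            mask = idx == j
            if mask.any():
                res_idx[mask] = _draw_categorical(u2[mask], T[:, j])
        resident[scale] = values[res_idx]

    # risk factors
    covariates: dict[str, np.ndarray] = {}
    for factor in cfg.risk_factors:
        u = rng.random(n)
        lev = np.zeros(n, dtype=np.int64)
        if abe.any():
            lev[abe] = _draw_categorical(u[abe], factor.case_probs)
        if (~abe).any():
            lev[~abe] = _draw_categorical(u[~abe], factor.control_probs)
        for c, col in enumerate(factor.columns):
            covariates[col] = np.array(
                [factor.levels[i][c] for i in lev], dtype=object)

    # peak bilirubin, truncated normal at 0 (cases drawn first)
    bili = np.zeros(n)
    for mask, mean, sd in (
        (abe, cfg.bilirubin.case_mean, cfg.bilirubin.case_sd),
        (~abe, cfg.bilirubin.control_mean, cfg.bilirubin.control_sd),
    ):
        m = int(mask.sum())
        if m:
            bili[mask] = stats.truncnorm.rvs(
                a=-mean / sd, b=np.inf, loc=mean, scale=sd, size=m,
                random_state=rng)
    bili = np.round(bili, 2)

    width = len(str(n))
    ids = np.array([f"I{i + 1:0{width}d}" for i in range(n)])
    rows = []
    for rater, scores in (("resident", resident), ("consultant", consultant)):
        d = {
            "infant_id": ids,
            "rater": rater,
            "mental_status": scores["mental_status"],
            "muscle_tone": scores["muscle_tone"],
            "cry": scores["cry"],
            "gaze": scores["gaze"],
            "abe_diagnosis": (abe.astype(int) if rater == "consultant"
                              else np.full(n, "", dtype=object)),
        }
        d.update({k: v for k, v in covariates.items()})
        d["peak_bilirubin"] = bili
        d["abe_truth"] = abe.astype(int)
        rows.append(pd.DataFrame(d))
    frame = (pd.concat(rows)
             .sort_values(["infant_id", "rater"], kind="stable")
             .reset_index(drop=True))
    return SyntheticCohort(frame, cfg)


# ---------------------------------------------------------------------------
# analytic agreement calibration
# ---------------------------------------------------------------------------

def _consultant_marginal(cfg: CohortConfig, field_name: str) -> np.ndarray:
    prev, mf = cfg.abe_prevalence, cfg.abe_mild_fraction
    prof = cfg.subscore_profiles
    abe = (mf * np.asarray(prof["abe_mild"][field_name])
           + (1 - mf) * np.asarray(prof["abe_severe"][field_name]))
    ctl = np.asarray(prof["control"][field_name])
    return prev * abe + (1 - prev) * ctl


def expected_kappa(p_stay: float, field_name: str = "mental_status",
                   config: Optional[CohortConfig] = None) -> float:
    """Population weighted kappa of the noise model at the given stay level.

    Builds the exact joint resident x consultant probability table implied by
    the profiles and the confusion kernel (no simulation) and evaluates the
    linearly weighted kappa on it.  Defined for the four sub-score fields;
    the total score has no single-kernel representation.
    """
    if field_name not in SUBSCALES:
        raise ValueError(f"expected_kappa is defined per sub-scale, got {field_name!r}")
    cfg = config if config is not None else CohortConfig()
    m = _consultant_marginal(cfg, field_name)
    T = noise_kernel(p_stay, len(m))
    joint = T * m[None, :]
    cats = default_categories(field_name)
    # joint is a probability table; scale to a large pseudo-count table only
    # to reuse the integer-count container (kappa is scale invariant)
    counts = np.round(joint * 1e12).astype(np.int64)
    return weighted_kappa(ContingencyTable(cats, counts)).estimate


def calibrate_noise(target_kappa: float, field_name: str = "mental_status",
                    config: Optional[CohortConfig] = None,
                    tol: float = 1e-4) -> float:
    """Stay probability whose expected weighted kappa matches the target.

    The expected kappa is increasing in ``p_stay`` (more staying, more
    agreement), so a bisection on [0, 1] converges; targets outside the
    reachable range [kappa(0), 1] raise :class:`CalibrationError`.
    """
    if not 0 < target_kappa <= 1.0:
        raise CalibrationError(f"target kappa must be in (0, 1], got {target_kappa}")
    if target_kappa == 1.0:
        return 1.0
    f = lambda p: expected_kappa(p, field_name, config)
    lo, hi = 0.0, 1.0
    if f(lo) >= target_kappa:
        # the kernel never reaches this little agreement for these profiles
        if f(lo) - target_kappa > tol:
            raise CalibrationError(
                f"target kappa {target_kappa} is below the minimum "
                f"{f(lo):.4f} reachable by adjacent-level noise")
        return lo
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if f(mid) < target_kappa:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)
    if abs(f(p) - target_kappa) > max(tol, 0.02):
        raise CalibrationError("bisection failed to reach the target kappa")
    return p
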