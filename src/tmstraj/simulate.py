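"""Synthetic cohorts with the statistical structure the trajectory models assume.

Two generators mirror the two model families:

* a latent-class generator — each patient belongs to one of K classes with a
  polynomial mean trajectory over weeks 0..6, plus a patient-level random
  intercept and i.i.d. weekly noise;
* an exponential-decay generator — each patient follows
  ``Change_i * exp(-t / B_i) + End_i`` with patient-level random effects on
  all three parameters (B on the log scale, keeping the time constant
  positive).

Defaults are calibrated to the registry cohort the package emulates: a
two-class (improvement / non-response) split of 40.76 / 59.24 %, baseline
PHQ-9 ~ N(17.86, 4.56^2), and class mean week-6 changes of -6.87 and -2.05
points.  Scores are clipped to the PHQ-9 range [0, 27] after noise; the
clipped fraction is tracked because the models themselves are unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import N_WEEKS, SCORE_MAX, SCORE_MIN, WEEKS, ValidationError, rng_from
from .curation import PatientSeries

__all__ = [
    "LcmmSimSpec",
    "DecaySimSpec",
    "simulate_lcmm_cohort",
    "simulate_decay_cohort",
    "simulate_registry",
    "simulate_covariates",
    "cohort_to_long_frame",
]

# Class mean-change cubics (intercept, linear, quadratic, cubic) on the week
# scale, solved so the week-6 change equals -6.87 (improvement) and -2.05
# (non-response) with an early-steep / near-flat shape respectively.
_IMPROVEMENT_COEF = (17.86, -2.0, 0.18, -1.35 / 216.0)
_NONRESPONSE_COEF = (17.86, -0.5, 0.045, -0.67 / 216.0)


@dataclass
class LcmmSimSpec:
    """Generating spec for the latent-class cohort.

    ``class_coefficients`` rows are (intercept, linear, quadratic, cubic) on
    the week scale; the intercept is the class mean baseline.  The
    random-intercept SD ``tau`` is the between-patient baseline spread, so
    raw week-0 scores are ~ N(intercept, tau^2).
    """

    n_patients: int = 238
    class_proportions: tuple = (0.4076, 0.5924)
    class_coefficients: tuple = (_IMPROVEMENT_COEF, _NONRESPONSE_COEF)
    tau: float = 4.56
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_proportions, float)
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValidationError("class proportions must be positive and sum to 1")
        if len(self.class_coefficients) != len(p):
            raise ValidationError("one coefficient row per class required")
        if self.tau < 0 or self.sigma <= 0:
            raise ValidationError("tau must be >= 0 and sigma > 0")


@dataclass
class DecaySimSpec:
    """Generating spec for the exponential-decay cohort.

    ``psi`` is the random-effect covariance on the (Change, log B, End)
    scale — B deviations are lognormal so the time constant stays positive.
    """

    n_patients: int = 240
    change: float = 12.0
    b: float = 2.11
    end: float = 6.0
    psi: np.ndarray = field(
        default_factory=lambda: np.diag([3.0**2, 0.25**2, 2.0**2])
    )
    sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        self.psi = np.asarray(self.psi, float)
        if self.b <= 0:
            raise ValidationError("population B must be positive")
        ev = np.linalg.eigvalsh((self.psi + self.psi.T) / 2)
        if self.psi.shape != (3, 3) or ev.min() < -1e-10:
            raise ValidationError("psi must be a 3x3 positive semi-definite matrix")


def _clip_report(scores: np.ndarray) -> tuple[np.ndarray, float]:
    clipped = (scores < SCORE_MIN) | (scores > SCORE_MAX)
    return np.clip(scores, SCORE_MIN, SCORE_MAX), float(clipped.mean())


def simulate_lcmm_cohort(
    spec: LcmmSimSpec, clip: bool = True
) -> tuple[list[PatientSeries], np.ndarray, dict]:
    """Draw a latent-class cohort.

    Returns (cohort, true class labels, info) where info records the
    clipped-cell fraction.  Deterministic under the spec seed.
    """
    rng = rng_from(spec.seed)
    p = np.asarray(spec.class_proportions, float)
    coefs = np.asarray(spec.class_coefficients, float)
    design = np.vander(WEEKS, N=coefs.shape[1], increasing=True)  # (7, deg+1)
    labels = rng.choice(len(p), size=spec.n_patients, p=p)
    shifts = rng.normal(0.0, spec.tau, size=spec.n_patients)
    noise = rng.normal(0.0, spec.sigma, size=(spec.n_patients, N_WEEKS))
    scores = design @ coefs[labels].T  # (7, n)
    scores = scores.T + shifts[:, None] + noise
    frac = 0.0
    if clip:
        scores, frac = _clip_report(scores)
    cohort = [
        PatientSeries(patient_id=f"P{i:04d}", weekly_scores=scores[i])
        for i in range(spec.n_patients)
    ]
    return cohort, labels, {"clipped_fraction": frac}


def simulate_decay_cohort(
    spec: DecaySimSpec, clip: bool = True
) -> tuple[list[PatientSeries], pd.DataFrame, dict]:
    """Draw an exponential-decay cohort.

    Returns (cohort, truth table with per-patient Change/B/End, info).
    """
    rng = rng_from(spec.seed)
    dev = rng.multivariate_normal(np.zeros(3), spec.psi, size=spec.n_patients)
    change_i = spec.change + dev[:, 0]
    b_i = np.maximum(spec.b * np.exp(dev[:, 1]), 0.1)
    end_i = spec.end + dev[:, 2]
    mean = change_i[:, None] * np.exp(-WEEKS[None, :] / b_i[:, None]) + end_i[:, None]
    scores = mean + rng.normal(0.0, spec.sigma, size=mean.shape)
    frac = 0.0
    if clip:
        scores, frac = _clip_report(scores)
    cohort = [
        PatientSeries(patient_id=f"P{i:04d}", weekly_scores=scores[i])
        for i in range(spec.n_patients)
    ]
    truth = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in cohort],
            "change": change_i,
            "b": b_i,
            "end": end_i,
        }
    )
    return cohort, truth, {"clipped_fraction": frac}


def simulate_registry(
    cohort: list[PatientSeries], dropout_rate: float, seed: int
) -> list[PatientSeries]:
    """Impose early-termination missingness on a complete cohort.

    Each patient independently, with probability ``dropout_rate``, has their
    series truncated after a uniformly chosen last observed week in 1..5;
    the result feeds ``curation.locf_extend``.
    """
    if not (0 <= dropout_rate < 1):
        raise ValidationError("dropout_rate must be in [0, 1)")
    rng = rng_from(seed)
    out = []
    for s in cohort:
        if rng.random() < dropout_rate:
            last = int(rng.integers(1, 6))
            y = s.weekly_scores.copy()
            y[last + 1 :] = np.nan
            out.append(s.replace(weekly_scores=y))
        else:
            out.append(s)
    return out


_COIL_LEVELS = ("F8", "H1", "switch")
_COIL_P = (0.605, 0.298, 0.097)
_PROTOCOL_LEVELS = ("high", "low", "iTBS", "switch")
_PROTOCOL_P = (0.349, 0.050, 0.437, 0.164)


def simulate_covariates(
    cohort: list[PatientSeries],
    labels: np.ndarray,
    seed: int,
    planted_feature: str | None = None,
    planted_log_or: float = 0.0,
) -> pd.DataFrame:
    """Generate a per-patient covariate table, independent of class by default.

    Categorical frequencies follow the emulated registry (60% F8 coil, 44%
    iTBS, 60% antianxiety use, ...).  If ``planted_feature`` names a numeric
    column, class membership is re-drawn with log-odds ``planted_log_or`` per
    SD of that feature, to give covariate-analysis tests a known signal.
    """
    rng = rng_from(seed)
    n = len(cohort)
    df = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in cohort],
            "coil": rng.choice(_COIL_LEVELS, size=n, p=_COIL_P),
            "protocol": rng.choice(_PROTOCOL_LEVELS, size=n, p=_PROTOCOL_P),
            "baseline": [s.weekly_scores[0] for s in cohort],
            "age": np.clip(rng.normal(44.9, 15.26, n), 18, 90),
            "sex_male": rng.random(n) < 0.366,
            "comorbid": rng.random(n) < 0.715,
            "antianxiety": rng.random(n) < 0.605,
            "treatment_year": rng.integers(1, 6, size=n),
            "class_label": np.asarray(labels, int),
        }
    )
    if planted_feature is not None and planted_log_or != 0.0:
        x = df[planted_feature].astype(float)
        z = (x - x.mean()) / x.std()
        logit = np.log(0.4076 / 0.5924) + planted_log_or * z
        p_improve = 1.0 / (1.0 + np.exp(-logit))
        df["class_label"] = (rng.random(n) >= p_improve).astype(int)
    return df


def cohort_to_long_frame(cohort: list[PatientSeries]) -> pd.DataFrame:
    """Long-format (patient_id, week, score) frame, as the curation CSV."""
    rows = []
    for s in cohort:
        for w in range(N_WEEKS):
            if not np.isnan(s.weekly_scores[w]):
                rows.append(
                    {"patient_id": s.patient_id, "week": w, "score": s.weekly_scores[w]}
                )
    return pd.DataFrame(rows)
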