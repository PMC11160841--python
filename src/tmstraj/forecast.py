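"""Forecasting the full treatment course from the first w weeks.

Two prediction paths mirror the two model families:

* LCMM path — class posteriors are computed from weeks 0..w under a fitted
  latent-class model (trained without the patient), and the predicted
  trajectory is the posterior-weighted average of class mean curves plus the
  posterior-weighted empirical-Bayes random intercept.
* decay path — with the time constant B fixed at the training population
  value, each observed week t >= 1 gives an estimate of the end score
  End_t = [y(t) - y(0) exp(-t/B)] / (1 - exp(-t/B)); these are combined by
  weighted least squares with weights (1 - exp(-t/B))^2 (the ML combination
  given fixed B and Change = y(0) - End).  The predicted trajectory re-enters
  the decay curve and is anchored at the observed baseline.

Predicted responder status always divides by the observed week-0 score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import N_WEEKS, ValidationError
from .curation import PatientSeries
from .lcmm import LcmmFit, class_curves, empirical_bayes_intercept, posterior

__all__ = [
    "Forecast",
    "lcmm_forecast",
    "decay_predict_end",
    "decay_forecast",
    "decay_to_class",
    "forecast_table",
]


@dataclass
class Forecast:
    """Predicted weeks 0..6 for one patient given data through week w."""

    patient_id: str
    max_modeled_week: int
    predicted: np.ndarray  # raw-score scale, 7 entries
    predicted_responder: bool
    class_posterior: np.ndarray | None = None
    predicted_class: int | None = None
    predicted_end: float | None = None

    def __post_init__(self):
        if not (0 <= self.max_modeled_week <= 6):
            raise ValidationError("max_modeled_week must be in 0..6")


def _responder_call(week0: float, pred6: float) -> bool:
    if week0 <= 0:
        return False
    return bool((week0 - pred6) / week0 >= 0.5)


def lcmm_forecast(fit: LcmmFit, series: PatientSeries, w: int) -> Forecast:
    """Posterior-weighted subject trajectory from weeks 0..w.

    Every week's prediction is the posterior-weighted mix of class means
    plus the posterior-weighted BLUP intercept; within the observed range
    this is subject-specific, beyond it the same quantities extrapolate.
    """
    if w > 6:
        raise ValidationError("w must be in 0..6")
    post = posterior(fit, series, w)
    curves = class_curves(fit)  # (K, 7) on the fit's scale
    blups = np.array(
        [empirical_bayes_intercept(fit, series, w, k) for k in range(fit.n_classes)]
    )
    pred = post @ curves + post @ blups
    y0 = float(series.weekly_scores[0])
    if fit.config.baseline_corrected:
        pred = pred - pred[0]  # corrected curves anchor at 0 by construction
        pred_raw = y0 + pred
    else:
        pred_raw = pred
    return Forecast(
        patient_id=series.patient_id,
        max_modeled_week=w,
        predicted=pred_raw,
        predicted_responder=_responder_call(y0, pred_raw[6]),
        class_posterior=post,
        predicted_class=int(np.argmax(post)),
    )


def decay_predict_end(
    series: PatientSeries, w: int, b_pop: float, end_fallback: float | None = None
) -> float:
    """End-score estimate from weeks 1..w with B fixed at the population value.

    With no post-baseline weeks (w = 0) the training population End fixed
    effect is returned; ``end_fallback`` must then be supplied.
    """
    if b_pop <= 0:
        raise ValidationError("b_pop must be positive")
    y = series.weekly_scores
    ts = [t for t in range(1, min(w, 6) + 1) if not np.isnan(y[t])]
    if not ts:
        if end_fallback is None:
            raise ValidationError("w = 0 requires the population End fallback")
        return float(end_fallback)
    t = np.array(ts, float)
    e = np.exp(-t / b_pop)
    ends = (y[ts] - y[0] * e) / (1.0 - e)
    wts = (1.0 - e) ** 2
    return float(np.sum(wts * ends) / np.sum(wts))


def decay_forecast(
    series: PatientSeries, w: int, b_pop: float, end_fallback: float | None = None
) -> Forecast:
    """Predicted trajectory from the end-score estimate re-entered in the curve.

    Change = y(0) - End, so the forecast is anchored at the observed
    baseline: predicted score(0) = y(0) always.
    """
    end = decay_predict_end(series, w, b_pop, end_fallback)
    y0 = float(series.weekly_scores[0])
    change = y0 - end
    t = np.arange(N_WEEKS, dtype=float)
    pred = change * np.exp(-t / b_pop) + end
    return Forecast(
        patient_id=series.patient_id,
        max_modeled_week=w,
        predicted=pred,
        predicted_responder=_responder_call(y0, pred[6]),
        predicted_end=end,
    )


def decay_to_class(forecast: Forecast, lcmm_fit: LcmmFit) -> tuple[int, np.ndarray]:
    """Class membership of a decay-predicted trajectory under a latent-class fit.

    The full predicted 7-week trajectory is scored by Bayes' rule against the
    fitted classes (baseline-corrected fits correct the predicted scores
    first); returns (modal class, posterior).
    """
    post = posterior(lcmm_fit, np.asarray(forecast.predicted, float), 6)
    return int(np.argmax(post)), post


def forecast_table(forecasts, cohort=None) -> pd.DataFrame:
    """Long-format forecast table: patient, w, week, predicted, source."""
    obs = {}
    if cohort is not None:
        obs = {s.patient_id: s.weekly_scores for s in cohort}
    rows = []
    for fc in forecasts:
        for week in range(N_WEEKS):
            rows.append(
                {
                    "patient_id": fc.patient_id,
                    "max_modeled_week": fc.max_modeled_week,
                    "week": week,
                    "observed": obs.get(fc.patient_id, [np.nan] * N_WEEKS)[week],
                    "predicted": fc.predicted[week],
                    "source": "subject" if week <= fc.max_modeled_week else "extrapolated",
                }
            )
    return pd.DataFrame(rows)
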