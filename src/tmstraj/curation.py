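"""Curation of longitudinal PHQ-9 records into analysis-ready weekly series.

A treatment course is modeled over weeks 0..6, where week 0 is the score
just before the first session and weeks 1..6 are arithmetic means of the
daily scores falling in half-open day windows [7(w-1), 7w) counted from the
first treatment day.  Patients who stop early have their final observed week
carried forward (LOCF); interior gaps (a missing week with later data) are
filled by linear interpolation between the flanking observed weeks and
flagged.  Response labels always come from raw (uncorrected) scores.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import N_WEEKS, SCORE_MAX, SCORE_MIN, ValidationError

__all__ = [
    "ScoreRecord",
    "PatientSeries",
    "ResponseLabel",
    "weekly_average",
    "locf_extend",
    "interpolate_interior",
    "baseline_correct",
    "label_response",
    "curate_cohort",
    "read_long_csv",
    "write_wide_csv",
    "cohort_matrix",
]


@dataclass(frozen=True)
class ScoreRecord:
    """A single daily symptom observation.

    Parameters
    ----------
    patient_id : opaque identifier
    day_index : days since the first treatment (>= 0)
    score : PHQ-9 total, in [0, 27]
    """

    patient_id: str
    day_index: int
    score: float

    def __post_init__(self):
        if self.day_index < 0:
            raise ValidationError(f"day_index must be >= 0, got {self.day_index}")
        if not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise ValidationError(f"score {self.score} outside [0, 27]")


@dataclass
class PatientSeries:
    """One patient's weekly scores over weeks 0..6.

    ``weekly_scores`` always has 7 entries; missing weeks are NaN until
    curation fills them.  ``carried_forward`` holds week indices filled by
    LOCF, ``interpolated`` those filled by interior interpolation.
    ``baseline_corrected`` marks series whose values are differences from
    the week-0 score (week 0 then being structurally zero).
    """

    patient_id: str
    weekly_scores: np.ndarray
    carried_forward: frozenset = frozenset()
    interpolated: frozenset = frozenset()
    covariates: dict = field(default_factory=dict)
    baseline_corrected: bool = False

    def __post_init__(self):
        self.weekly_scores = np.asarray(self.weekly_scores, dtype=float)
        if self.weekly_scores.shape != (N_WEEKS,):
            raise ValidationError(
                f"weekly_scores must have exactly {N_WEEKS} entries"
            )
        if 0 in self.carried_forward:
            raise ValidationError("week 0 can never be carried forward")
        obs = self.weekly_scores[~np.isnan(self.weekly_scores)]
        if not self.baseline_corrected and obs.size and (
            obs.min() < SCORE_MIN - 1e-9 or obs.max() > SCORE_MAX + 1e-9
        ):
            raise ValidationError("raw weekly scores must lie in [0, 27]")

    @property
    def observed_weeks(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.weekly_scores))

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.weekly_scores).any()

    def replace(self, **kw) -> "PatientSeries":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ResponseLabel:
    """Dichotomous end-of-course outcome for one patient."""

    responder_50: bool
    class_label: int | None = None


def weekly_average(
    records: Iterable[ScoreRecord], baseline: float, patient_id: str | None = None
) -> PatientSeries:
    """Collapse daily records into weekly means; week 0 is the baseline score.

    Week w >= 1 averages scores with day_index in [7(w-1), 7w); weeks without
    records stay NaN for downstream LOCF/interpolation.
    """
    records = list(records)
    if patient_id is None:
        patient_id = records[0].patient_id if records else "unknown"
    if not (SCORE_MIN <= baseline <= SCORE_MAX):
        raise ValidationError(f"baseline {baseline} outside [0, 27]")
    scores = np.full(N_WEEKS, np.nan)
    scores[0] = baseline
    buckets: dict[int, list[float]] = {}
    for r in records:
        week = r.day_index // 7 + 1
        if week > 6:
            raise ValidationError(
                f"record at day {r.day_index} lies beyond the week-6 window"
            )
        buckets.setdefault(week, []).append(r.score)
    for w, vals in buckets.items():
        scores[w] = float(np.mean(vals))
    return PatientSeries(patient_id=patient_id, weekly_scores=scores)


def interpolate_interior(series: PatientSeries) -> PatientSeries:
    """Fill interior gaps by linear interpolation between flanking weeks."""
    y = series.weekly_scores.copy()
    obs = series.observed_weeks
    if obs.size == 0:
        return series
    filled = set()
    last = obs.max()
    for w in range(N_WEEKS):
        if np.isnan(y[w]) and w < last:
            lo = obs[obs < w].max()
            hi = obs[obs > w].min()
            y[w] = y[lo] + (y[hi] - y[lo]) * (w - lo) / (hi - lo)
            filled.add(w)
    return series.replace(
        weekly_scores=y, interpolated=series.interpolated | frozenset(filled)
    )


def locf_extend(series: PatientSeries) -> PatientSeries:
    """Carry the final observed week forward to week 6.

    Requires at least one post-baseline week; a baseline-only series is
    rejected (the patient has no usable course data).
    """
    obs = series.observed_weeks
    if 0 not in obs:
        raise ValidationError(f"patient {series.patient_id}: no week-0 baseline")
    if obs.max() < 1:
        raise ValidationError(
            f"patient {series.patient_id}: only week 0 observed; excluded"
        )
    interior = np.setdiff1d(np.arange(obs.max()), obs)
    if interior.size:
        raise ValidationError(
            f"patient {series.patient_id}: interior gap at weeks {interior.tolist()};"
            " run interpolate_interior first"
        )
    y = series.weekly_scores.copy()
    last = int(obs.max())
    filled = set(range(last + 1, N_WEEKS))
    y[last + 1 :] = y[last]
    return series.replace(
        weekly_scores=y, carried_forward=series.carried_forward | frozenset(filled)
    )


def baseline_correct(series: PatientSeries) -> PatientSeries:
    """Subtract the week-0 score from every weekly value (week 0 becomes 0)."""
    y = series.weekly_scores
    if np.isnan(y[0]):
        raise ValidationError("week 0 missing; cannot baseline-correct")
    return series.replace(weekly_scores=y - y[0], baseline_corrected=True)


def label_response(series: PatientSeries) -> ResponseLabel:
    """50%-reduction responder label from raw week-0 and week-6 scores.

    The threshold is inclusive (reduction >= half the baseline); a zero
    baseline is a non-responder by convention.
    """
    if series.baseline_corrected:
        raise ValidationError("labels are computed on raw scores only")
    y = series.weekly_scores
    if np.isnan(y[6]):
        raise ValidationError("week 6 missing; curate (LOCF) before labeling")
    w0, w6 = y[0], y[6]
    if w0 <= 0:
        return ResponseLabel(responder_50=False)
    return ResponseLabel(responder_50=bool((w0 - w6) / w0 >= 0.5))


def curate_cohort(
    cohort: Sequence[PatientSeries],
) -> tuple[list[PatientSeries], dict]:
    """Run the full curation pass over a cohort.

    Interpolates interior gaps, LOCF-extends trailing gaps, and excludes
    patients lacking week 0 or any post-baseline week.  Returns the curated
    cohort and a report dict (exclusions, carried-forward / interpolated
    cell counts).
    """
    curated: list[PatientSeries] = []
    excluded: list[dict] = []
    n_cf = n_interp = 0
    for s in cohort:
        try:
            s2 = locf_extend(interpolate_interior(s))
        except ValidationError as e:
            excluded.append({"patient_id": str(s.patient_id), "reason": str(e)})
            continue
        n_cf += len(s2.carried_forward)
        n_interp += len(s2.interpolated)
        curated.append(s2)
    report = {
        "n_input": len(cohort),
        "n_curated": len(curated),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "carried_forward_cells": n_cf,
        "interpolated_cells": n_interp,
        "total_cells": len(curated) * N_WEEKS,
    }
    return curated, report


# ---------------------------------------------------------------------------
# I/O


def read_long_csv(path, covariates_path=None) -> list[PatientSeries]:
    """Read a long-format CSV (patient_id, day_index|week, score) into series.

    If a ``week`` column is present, values are taken as already-weekly
    scores (week 0 = baseline); otherwise daily records are averaged.
    An optional wide covariate CSV keyed by patient_id is merged in.
    """
    df = pd.read_csv(path)
    cov = {}
    if covariates_path is not None:
        cdf = pd.read_csv(covariates_path)
        cov = {
            str(r["patient_id"]): {k: r[k] for k in cdf.columns if k != "patient_id"}
            for _, r in cdf.iterrows()
        }
    out = []
    for pid, g in df.groupby("patient_id", sort=True):
        pid = str(pid)
        if "week" in g.columns:
            scores = np.full(N_WEEKS, np.nan)
            for _, r in g.iterrows():
                scores[int(r["week"])] = float(r["score"])
            s = PatientSeries(patient_id=pid, weekly_scores=scores)
        else:
            base_rows = g[g["day_index"] < 0]
            if len(base_rows):
                baseline = float(base_rows["score"].mean())
                g = g[g["day_index"] >= 0]
            else:
                raise ValidationError(
                    f"patient {pid}: no baseline row (day_index < 0) in daily CSV"
                )
            recs = [
                ScoreRecord(pid, int(r["day_index"]), float(r["score"]))
                for _, r in g.iterrows()
            ]
            s = weekly_average(recs, baseline, patient_id=pid)
        if pid in cov:
            s.covariates.update(cov[pid])
        out.append(s)
    return out


def write_wide_csv(cohort: Sequence[PatientSeries], path, report=None, report_path=None):
    """Write a curated cohort as a wide patient x week CSV (+ JSON report)."""
    rows = []
    for s in cohort:
        row = {"patient_id": s.patient_id}
        row.update({f"week_{w}": s.weekly_scores[w] for w in range(N_WEEKS)})
        row["carried_forward"] = ";".join(map(str, sorted(s.carried_forward)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if report is not None and report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)


def read_wide_csv(path) -> list[PatientSeries]:
    df = pd.read_csv(path, comment="#")
    out = []
    for _, r in df.iterrows():
        cf = frozenset(
            int(x) for x in str(r.get("carried_forward", "")).split(";") if x not in ("", "nan")
        )
        scores = np.array([r[f"week_{w}"] for w in range(N_WEEKS)], dtype=float)
        out.append(
            PatientSeries(
                patient_id=str(r["patient_id"]), weekly_scores=scores, carried_forward=cf
            )
        )
    return out


def cohort_matrix(cohort: Sequence[PatientSeries]) -> np.ndarray:
    """Stack a cohort into an (n, 7) score matrix."""
    return np.vstack([s.weekly_scores for s in cohort])
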