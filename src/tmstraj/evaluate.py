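"""Cross-validated model selection and predictive-power evaluation.

This module holds the machinery behind the package's two summary tables:

* a model-selection table over the latent-class candidate grid (classes 1-5
  x polynomial degree L/LQ/LQC x raw vs baseline-corrected), with
  fold-averaged BIC/SABIC, test-set correlation and minimum class share; and
* a prediction-experiment table indexed by the maximum modeled week w: train
  on complete courses, forecast held-out patients from weeks 0..w only, and
  score sensitivity, specificity and AUC (with stratified-bootstrap CIs) for
  two response definitions, plus the Pearson correlation of predicted vs
  observed scores.

AUC of a dichotomous prediction is the ROC area of the two-level score,
which equals (sensitivity + specificity) / 2 — balanced accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import N_WEEKS, ValidationError, child_seed, rng_from
from .curation import PatientSeries, label_response
from .decay import fit_nlme
from .forecast import decay_forecast, decay_to_class, lcmm_forecast
from .lcmm import LcmmConfig, assign_classes, fit as lcmm_fit_op

__all__ = [
    "FoldPlan",
    "EvalReport",
    "make_folds",
    "confusion_metrics",
    "auc_binary",
    "bootstrap_ci",
    "score_correlation",
    "select_lcmm",
    "prediction_experiment",
    "plot_auc_by_week",
]


@dataclass
class FoldPlan:
    """Assignment of patients to k cross-validation folds."""

    k: int
    assignment: dict  # patient_id -> fold index
    labels: dict
    notes: list = field(default_factory=list)

    def fold_ids(self, fold: int) -> list:
        return [pid for pid, f in self.assignment.items() if f == fold]


def make_folds(labels: dict, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k folds: within each label stratum, patients are shuffled
    and dealt round-robin, with the fold counter running across strata so
    overall fold sizes differ by at most one.

    Strata smaller than k cannot be represented in every fold; they are
    dealt the same way (plain randomization within the stratum) and noted.
    """
    ids = list(labels.keys())
    if k > len(ids):
        raise ValidationError("k exceeds the number of patients")
    rng = rng_from(seed)
    notes = []
    assignment = {}
    counter = 0
    strata = {}
    for pid in ids:
        strata.setdefault(labels[pid], []).append(pid)
    fold_order = rng.permutation(k)
    for lab in sorted(strata, key=str):
        members = sorted(strata[lab], key=str)
        rng.shuffle(members)
        if len(members) < k:
            notes.append(f"stratum {lab!r} has {len(members)} < k={k} members; plain randomization")
        for pid in members:
            assignment[pid] = int(fold_order[counter % k])
            counter += 1
    return FoldPlan(k=k, assignment=assignment, labels=dict(labels), notes=notes)


def confusion_metrics(predicted, observed) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP)).

    With a single-class observed vector the undefined metric is NaN.
    """
    predicted = np.asarray(predicted, bool)
    observed = np.asarray(observed, bool)
    n_pos = observed.sum()
    n_neg = (~observed).sum()
    sens = float((predicted & observed).sum() / n_pos) if n_pos else float("nan")
    spec = float((~predicted & ~observed).sum() / n_neg) if n_neg else float("nan")
    return sens, spec


def auc_binary(predicted, observed) -> float:
    """ROC area of a binary predictor: (sensitivity + specificity) / 2."""
    sens, spec = confusion_metrics(predicted, observed)
    return (sens + spec) / 2.0


_METRICS = {
    "sensitivity": lambda p, o: confusion_metrics(p, o)[0],
    "specificity": lambda p, o: confusion_metrics(p, o)[1],
    "auc": auc_binary,
}


def bootstrap_ci(
    predicted, observed, metric="auc", n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI over stratified bootstrap replicates.

    Resampling is within observed-label strata, so every replicate keeps
    both classes whenever the input has them.  The named metrics are
    computed vectorized; a callable metric falls back to a Python loop.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    predicted = np.asarray(predicted, bool)
    observed = np.asarray(observed, bool)
    rng = rng_from(seed)
    pos = np.flatnonzero(observed)
    neg = np.flatnonzero(~observed)
    if callable(metric):
        vals = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
            )
            vals.append(metric(predicted[idx], observed[idx]))
        vals = np.asarray(vals, float)
    else:
        if metric not in _METRICS:
            raise ValidationError(f"unknown metric {metric!r}")
        # sensitivity over replicates = mean of resampled positive predictions
        sens = spec = None
        if pos.size and metric in ("sensitivity", "auc"):
            draw = rng.integers(0, pos.size, size=(n_boot, pos.size))
            sens = predicted[pos][draw].mean(axis=1)
        if neg.size and metric in ("specificity", "auc"):
            draw = rng.integers(0, neg.size, size=(n_boot, neg.size))
            spec = 1.0 - predicted[neg][draw].mean(axis=1)
        if metric == "sensitivity":
            vals = sens
        elif metric == "specificity":
            vals = spec
        else:
            if sens is None or spec is None:
                return float("nan"), float("nan")
            vals = (sens + spec) / 2.0
        if vals is None:
            return float("nan"), float("nan")
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def score_correlation(predicted, observed) -> tuple[float, tuple[float, float]]:
    """Pearson r over pooled pairs, with a Fisher-z 95% CI."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan"), (float("nan"), float("nan"))
    r = float(stats.pearsonr(predicted, observed)[0])
    n = predicted.size
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return r, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Model selection over the latent-class grid


def _min_class_share(fit) -> float:
    counts = np.bincount(
        np.argmax(fit.posterior_matrix, axis=1), minlength=fit.n_classes
    )
    return float(counts.min() / counts.sum() * 100.0)


def _has_flat_class(fit, threshold: float = 2.5) -> bool:
    """True when some class improves by less than `threshold` points by week 6."""
    return bool((fit.week6_change() > -threshold).any())


def select_lcmm(
    cohort,
    n_classes_grid=(1, 2, 3, 4, 5),
    degree_grid=(1, 2, 3),
    modes=(False, True),
    k: int = 5,
    seed: int = 0,
    n_starts: int = 10,
    min_share_pct: float = 5.0,
) -> tuple[pd.DataFrame, dict | None]:
    """Fold-averaged fit statistics for every candidate latent-class model.

    For each (baseline-corrected?, degree, K) the cohort is split into k
    plain-random folds; the model is fit on each training set, its BIC and
    SABIC recorded, and held-out patients' full trajectories forecast from
    all 7 weeks to give a test-set predicted-vs-observed correlation.
    Delta columns subtract the more complex model's criterion from the less
    complex one's (positive favors complexity), between adjacent polynomial
    orders within class count and adjacent class counts within order.
    Configurations whose smallest class holds < 5% of the sample are
    flagged; the automatic choice is the best-BIC unflagged row.
    """
    ids = {s.patient_id: 0 for s in cohort}
    plan = make_folds(ids, k=k, seed=child_seed(seed, "select-folds"))
    by_id = {s.patient_id: s for s in cohort}
    rows = []
    for bc, d, K in itertools.product(modes, degree_grid, n_classes_grid):
        cfg = LcmmConfig(
            n_classes=K, degree=d, baseline_corrected=bc,
            n_starts=n_starts, seed=child_seed(seed, f"fit-{bc}-{d}-{K}"),
        )
        bics, sabics, shares, flats = [], [], [], []
        pred_all, obs_all = [], []
        failures = 0
        for f in range(k):
            train = [by_id[p] for p, ff in plan.assignment.items() if ff != f]
            test = [by_id[p] for p, ff in plan.assignment.items() if ff == f]
            try:
                fit = lcmm_fit_op(train, cfg)
            except ValidationError:
                failures += 1
                continue
            bics.append(fit.bic)
            sabics.append(fit.sabic)
            shares.append(_min_class_share(fit))
            flats.append(_has_flat_class(fit))
            for s in test:
                fc = lcmm_forecast(fit, s, 6)
                pred_all.extend(fc.predicted)
                obs_all.extend(s.weekly_scores)
        if not bics:
            rows.append(
                dict(baseline_corrected=bc, degree=d, n_classes=K, bic=np.nan,
                     sabic=np.nan, test_r=np.nan, min_class_share=np.nan,
                     flat_class=False, n_failed_folds=failures, flagged=True)
            )
            continue
        r, _ = score_correlation(pred_all, obs_all)
        rows.append(
            dict(
                baseline_corrected=bc, degree=d, n_classes=K,
                bic=float(np.mean(bics)), sabic=float(np.mean(sabics)),
                test_r=r, min_class_share=float(np.mean(shares)),
                flat_class=bool(np.any(flats)), n_failed_folds=failures,
                flagged=bool(np.mean(shares) < min_share_pct),
            )
        )
    table = pd.DataFrame(rows)
    for crit in ("bic", "sabic"):
        dpoly = np.full(len(table), np.nan)
        dclass = np.full(len(table), np.nan)
        for i, row in table.iterrows():
            simpler_poly = table[
                (table.baseline_corrected == row.baseline_corrected)
                & (table.n_classes == row.n_classes)
                & (table.degree == row.degree - 1)
            ]
            if len(simpler_poly):
                dpoly[i] = simpler_poly.iloc[0][crit] - row[crit]
            simpler_cls = table[
                (table.baseline_corrected == row.baseline_corrected)
                & (table.degree == row.degree)
                & (table.n_classes == row.n_classes - 1)
            ]
            if len(simpler_cls):
                dclass[i] = simpler_cls.iloc[0][crit] - row[crit]
        table[f"delta_{crit}_polynomial"] = dpoly
        table[f"delta_{crit}_class"] = dclass
    ok = table[~table.flagged & table.bic.notna()]
    chosen = None
    if len(ok):
        best = ok.loc[ok.bic.idxmin()]
        chosen = dict(
            baseline_corrected=bool(best.baseline_corrected),
            degree=int(best.degree),
            n_classes=int(best.n_classes),
        )
    return table, chosen


# ---------------------------------------------------------------------------
# Prediction experiment (the week-by-week forecasting table)


@dataclass
class EvalReport:
    """Fold-averaged forecasting metrics per (model, response definition, w)."""

    rows: pd.DataFrame  # averaged across folds
    per_fold: pd.DataFrame
    fold_plan: FoldPlan
    model: str


_MODELS = ("lcmm-raw", "lcmm-bc", "decay")
_RESPONSE_DEFS = ("fifty_percent", "improvement_class")


def prediction_experiment(
    cohort,
    model: str,
    seed: int = 0,
    k: int = 5,
    n_classes: int = 2,
    degree: int = 3,
    n_starts: int = 10,
    n_boot: int = 2000,
    reference_fit=None,
) -> EvalReport:
    """Forecast held-out patients from weeks 0..w for every w in 0..6.

    ``model`` is one of "lcmm-raw", "lcmm-bc" (latent-class fits on raw or
    baseline-corrected scores) or "decay" (exponential-decay NLME whose
    population time constant drives the week-w end-score forecast).  Both
    response definitions are always evaluated: the inclusive 50%-reduction
    rule, and membership in the improvement trajectory of the full-cohort
    reference latent-class fit (supplied via ``reference_fit`` or fit here),
    the mild train/test leakage of that definition being inherent to the
    design.  Folds are stratified on the reference trajectory classes.
    Metrics are computed per fold and then averaged.
    """
    if model not in _MODELS:
        raise ValidationError(f"model must be one of {_MODELS}")
    cohort = list(cohort)
    if len(cohort) < 50:
        raise ValidationError("prediction experiment needs n >= 50")
    by_id = {s.patient_id: s for s in cohort}
    # reference full-cohort latent-class fit -> improvement-class truth
    if reference_fit is None:
        ref_cfg = LcmmConfig(
            n_classes=n_classes, degree=degree, baseline_corrected=True,
            n_starts=n_starts, seed=child_seed(seed, "reference-fit"),
        )
        reference_fit = lcmm_fit_op(cohort, ref_cfg)
    ref_assign = assign_classes(reference_fit, cohort).assignments
    improv_truth = {pid: cls == 0 for pid, (cls, _) in ref_assign.items()}
    resp_truth = {s.patient_id: label_response(s).responder_50 for s in cohort}
    plan = make_folds(
        {pid: cls for pid, (cls, _) in ref_assign.items()},
        k=k,
        seed=child_seed(seed, "cv-folds"),
    )

    fold_rows = []
    for f in range(plan.k):
        train = [by_id[p] for p, ff in plan.assignment.items() if ff != f]
        test = [by_id[p] for p, ff in plan.assignment.items() if ff == f]
        # train the fold's model(s) on complete courses
        lcmm_trained = None
        decay_trained = None
        if model in ("lcmm-raw", "lcmm-bc"):
            cfg = LcmmConfig(
                n_classes=n_classes, degree=degree,
                baseline_corrected=(model == "lcmm-bc"),
                n_starts=n_starts, seed=child_seed(seed, f"fold{f}-lcmm"),
            )
            lcmm_trained = lcmm_fit_op(train, cfg)
        else:
            decay_trained = fit_nlme(train)
            # class membership of decay forecasts is read off a latent-class
            # fit trained on the same folds
            cfg = LcmmConfig(
                n_classes=n_classes, degree=degree, baseline_corrected=True,
                n_starts=n_starts, seed=child_seed(seed, f"fold{f}-lcmm"),
            )
            lcmm_trained = lcmm_fit_op(train, cfg)
        for w in range(N_WEEKS):
            pred_scores, obs_scores = [], []
            calls = {rd: [] for rd in _RESPONSE_DEFS}
            truths = {rd: [] for rd in _RESPONSE_DEFS}
            for s in test:
                if model == "decay":
                    fc = decay_forecast(
                        s, w, decay_trained.params.b,
                        end_fallback=decay_trained.params.end,
                    )
                    cls = decay_to_class(fc, lcmm_trained)[0]
                else:
                    fc = lcmm_forecast(lcmm_trained, s, w)
                    cls = fc.predicted_class
                pred_scores.extend(fc.predicted)
                obs_scores.extend(s.weekly_scores)
                calls["fifty_percent"].append(fc.predicted_responder)
                truths["fifty_percent"].append(resp_truth[s.patient_id])
                calls["improvement_class"].append(cls == 0)
                truths["improvement_class"].append(improv_truth[s.patient_id])
            r, (r_lo, r_hi) = score_correlation(pred_scores, obs_scores)
            for rd in _RESPONSE_DEFS:
                p = np.array(calls[rd])
                o = np.array(truths[rd])
                sens, spec = confusion_metrics(p, o)
                auc = (sens + spec) / 2.0
                lo, hi = bootstrap_ci(
                    p, o, "auc", n_boot=n_boot,
                    seed=child_seed(seed, f"boot-{f}-{w}-{rd}"),
                )
                fold_rows.append(
                    dict(model=model, response_def=rd, w=w, fold=f,
                         sensitivity=sens, specificity=spec, auc=auc,
                         auc_lo=lo, auc_hi=hi, r=r, r_lo=r_lo, r_hi=r_hi)
                )
    per_fold = pd.DataFrame(fold_rows)
    avg = (
        per_fold.drop(columns="fold")
        .groupby(["model", "response_def", "w"], as_index=False)
        .mean()
    )
    return EvalReport(rows=avg, per_fold=per_fold, fold_plan=plan, model=model)


def plot_auc_by_week(reports, path):
    """AUC-versus-max-modeled-week panel chart, one column per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(reports, (list, tuple)):
        reports = [reports]
    fig, axes = plt.subplots(
        2, len(reports), figsize=(4 * len(reports), 6), squeeze=False, sharey=True
    )
    for j, rep in enumerate(reports):
        for i, rd in enumerate(_RESPONSE_DEFS):
            sub = rep.rows[rep.rows.response_def == rd]
            ax = axes[i][j]
            ax.errorbar(
                sub.w, sub.auc,
                yerr=[sub.auc - sub.auc_lo, sub.auc_hi - sub.auc],
                fmt="o-", capsize=3,
            )
            ax.axhline(0.5, ls="--", color="gray")
            ax.set_ylim(0, 1.05)
            ax.set_xlabel("max modeled week")
            if j == 0:
                ax.set_ylabel(f"AUC\n({rd})")
            if i == 0:
                ax.set_title(rep.model)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
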