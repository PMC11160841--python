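"""Do coil, protocol or patient characteristics predict trajectory class?

The analysis mirrors a standard post-hoc membership workflow: balance the
class distribution with SMOTE (interpolating between minority-class
neighbors; categorical attributes are copied from the seed point and
synthetic points inherit its membership weight), fit multinomial logistic
regressions weighted by each patient's modal-class posterior probability,
and keep predictors by greedy forward selection only when they cut BIC by
more than 5.  Coil and protocol are collinear by design of the emulated
registry and are never analyzed in the same model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.neighbors import NearestNeighbors

from ._utils import ValidationError, rng_from

__all__ = [
    "build_covariate_table",
    "smote_balance",
    "weighted_multinomial_fit",
    "forward_select",
]

_EXCLUSIVE = ("coil", "protocol")


def build_covariate_table(
    features: pd.DataFrame, class_labels, weights=None, exclude_switch: str | None = None
) -> pd.DataFrame:
    """Assemble the analysis table: features + class label + membership weight.

    ``exclude_switch`` drops patients whose coil (or protocol) is "switch",
    as those patients cannot be attributed to either arm of that factor.
    """
    df = features.copy()
    df["class_label"] = np.asarray(class_labels, int)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    if (w <= 0).any() or (w > 1).any():
        raise ValidationError("membership weights must lie in (0, 1]")
    df["weight"] = w
    if exclude_switch is not None:
        df = df[df[exclude_switch] != "switch"].reset_index(drop=True)
    return df


def _split_feature_types(df: pd.DataFrame, features) -> tuple[list, list]:
    num, cat = [], []
    for f in features:
        if pd.api.types.is_numeric_dtype(df[f]) and not pd.api.types.is_bool_dtype(df[f]):
            num.append(f)
        else:
            cat.append(f)
    return num, cat


def smote_balance(
    table: pd.DataFrame,
    features,
    class_col: str = "class_label",
    k_neighbors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Oversample minority classes to parity by neighbor interpolation.

    Numeric features of a synthetic point lie on the segment between a
    minority point and one of its k nearest minority neighbors (distances on
    standardized numerics); categorical features and the membership weight
    are copied from the seed point.  Majority-class rows are returned
    untouched; an already balanced table is returned unchanged.
    """
    counts = table[class_col].value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least two classes to balance")
    target = counts.max()
    if (counts == target).all():
        return table.copy()
    rng = rng_from(seed)
    num, cat = _split_feature_types(table, features)
    out = [table.copy()]
    for cls, cnt in counts.items():
        need = int(target - cnt)
        if need == 0:
            continue
        sub = table[table[class_col] == cls].reset_index(drop=True)
        if len(sub) == 1:
            synth = pd.concat([sub] * need, ignore_index=True)
            out.append(synth)
            warnings.warn(f"class {cls!r} has a single member; duplicated without jitter")
            continue
        Xn = sub[num].to_numpy(float) if num else np.zeros((len(sub), 1))
        scale = Xn.std(axis=0)
        scale[scale == 0] = 1.0
        kk = min(k_neighbors, len(sub) - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(Xn / scale)
        _, nbr = nn.kneighbors(Xn / scale)
        seeds = rng.integers(0, len(sub), size=need)
        picks = nbr[seeds, rng.integers(1, kk + 1, size=need)]
        u = rng.random(need)
        synth = sub.iloc[seeds].reset_index(drop=True).copy()
        if num:
            a = sub[num].to_numpy(float)[seeds]
            b = sub[num].to_numpy(float)[picks]
            synth[num] = a + u[:, None] * (b - a)
        out.append(synth)
    return pd.concat(out, ignore_index=True)


def _design_matrix(table, features, stats=None):
    """Standardized numeric + one-hot (drop-first) categorical design."""
    num, cat = _split_feature_types(table, features)
    cols, names = [np.ones(len(table))], ["intercept"]
    if stats is None:
        stats = {}
        for f in num:
            x = table[f].to_numpy(float)
            stats[f] = (x.mean(), x.std() if x.std() > 0 else 1.0)
    for f in num:
        m, s = stats[f]
        cols.append((table[f].to_numpy(float) - m) / s)
        names.append(f)
    for f in cat:
        levels = sorted(pd.unique(table[f].astype(str)))
        for lev in levels[1:]:
            cols.append((table[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names, stats


def _check_exclusive(features):
    if all(f in features for f in _EXCLUSIVE):
        raise ValidationError("coil and protocol are never analyzed in the same model")


def weighted_multinomial_fit(
    table: pd.DataFrame,
    features,
    class_col: str = "class_label",
    weight_col: str = "weight",
    ridge: float = 0.0,
) -> dict:
    """Maximize the weight-multiplied multinomial log-likelihood.

    The largest class is the reference.  BIC uses n = sum of weights.
    Near-perfect separation (runaway coefficients) triggers a
    ridge-stabilized refit with a warning.
    """
    _check_exclusive(features)
    y_raw = table[class_col].to_numpy()
    classes = list(pd.Series(y_raw).value_counts().index)  # largest first
    ref = classes[0]
    others = [c for c in classes if c != ref]
    y_idx = np.array([others.index(c) + 1 if c != ref else 0 for c in y_raw])
    w = table[weight_col].to_numpy(float) if weight_col in table else np.ones(len(table))
    X, names, stats = _design_matrix(table, features)
    n, p = X.shape
    m = len(others)

    def negll(theta):
        B = theta.reshape(m, p)
        eta = np.column_stack([np.zeros(n), X @ B.T])  # (n, m+1)
        lse = logsumexp(eta, axis=1)
        ll = float((w * (eta[np.arange(n), y_idx] - lse)).sum())
        P = np.exp(eta - lse[:, None])
        G = np.empty((m, p))
        for j in range(m):
            ind = (y_idx == j + 1).astype(float)
            G[j] = -((w * (ind - P[:, j + 1]))[:, None] * X).sum(axis=0)
        pen = 0.5 * ridge * (theta**2).sum()
        return -ll + pen, G.ravel() + ridge * theta

    theta0 = np.zeros(m * p)
    sol = minimize(negll, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
    if ridge == 0.0 and np.abs(sol.x).max() > 30.0:
        warnings.warn("possible perfect separation; refitting with a small ridge")
        return weighted_multinomial_fit(
            table, features, class_col, weight_col, ridge=1e-4
        )
    B = sol.x.reshape(m, p)
    pen = 0.5 * ridge * (sol.x**2).sum()
    ll = -(sol.fun - pen)
    n_eff = w.sum()
    n_params = m * p
    bic = -2 * ll + n_params * np.log(n_eff)
    coef = pd.DataFrame(B, columns=names, index=[f"{c}_vs_{ref}" for c in others])
    return {
        "coefficients": coef,
        "loglik": float(ll),
        "bic": float(bic),
        "n_params": n_params,
        "reference_class": ref,
        "feature_names": names,
        "converged": bool(sol.success),
    }


def forward_select(
    table: pd.DataFrame,
    candidates,
    class_col: str = "class_label",
    weight_col: str = "weight",
    min_bic_drop: float = 5.0,
) -> tuple[list, pd.DataFrame]:
    """Greedy forward selection under a BIC-reduction-greater-than-5 rule.

    Starting from the intercept-only model, each step adds the candidate
    with the largest BIC reduction, but only if that reduction exceeds
    ``min_bic_drop``; otherwise selection stops.  Returns the selected
    feature list and a step log.
    """
    _check_exclusive(candidates)
    selected: list = []
    null = weighted_multinomial_fit(table, selected, class_col, weight_col)
    current_bic = null["bic"]
    log_rows = [dict(step=0, added=None, bic=current_bic, delta=np.nan, accepted=True)]
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        trials = []
        for f in remaining:
            res = weighted_multinomial_fit(
                table, selected + [f], class_col, weight_col
            )
            trials.append((current_bic - res["bic"], f, res["bic"]))
        drop, best_f, best_bic = max(trials)
        if drop > min_bic_drop:
            selected.append(best_f)
            remaining.remove(best_f)
            current_bic = best_bic
            log_rows.append(
                dict(step=step, added=best_f, bic=best_bic, delta=drop, accepted=True)
            )
        else:
            log_rows.append(
                dict(step=step, added=best_f, bic=best_bic, delta=drop, accepted=False)
            )
            break
    return selected, pd.DataFrame(log_rows)
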