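"""Latent class linear mixed models for weekly symptom trajectories.

The model: each patient i belongs to an unobserved class k with probability
pi_k; within class k the 7-week score vector is

    y_i | k  ~  N(X beta_k,  tau^2 J + sigma^2 I)

with X the polynomial design on weeks (degree 1-3), a patient-level random
intercept of variance tau^2 shared across classes (J the all-ones matrix),
and i.i.d. residual variance sigma^2.  Estimation is by EM with closed-form
M-steps; the structured covariance makes every per-class density and GLS
update O(T^2) via the rank-one eigenstructure of tau^2 J + sigma^2 I.

Baseline-corrected fits model differences from the week-0 score; the
structurally-zero week 0 is dropped from the likelihood (it would otherwise
force a degenerate residual variance).

Classes are canonically ordered by fitted week-6 mean change, most
improvement first, so labels are stable across fits and folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from ._utils import N_WEEKS, ValidationError, rng_from
from .curation import PatientSeries, cohort_matrix

__all__ = [
    "LcmmConfig",
    "LcmmFit",
    "ClassAssignment",
    "marginal_loglik",
    "fit",
    "information_criteria",
    "posterior",
    "empirical_bayes_intercept",
    "assign_classes",
    "class_curves",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LcmmConfig:
    """Estimation settings for one latent-class fit.

    ``n_classes`` in 1..5 and polynomial ``degree`` in {1 (L), 2 (LQ),
    3 (LQC)} span the candidate grid; ``baseline_corrected`` selects the
    difference-from-baseline variant.
    """

    n_classes: int = 2
    degree: int = 3
    baseline_corrected: bool = True
    n_starts: int = 20
    max_iter: int = 2000
    rel_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.n_classes > 5:
            raise ValidationError("n_classes must be in 1..5")
        if self.degree not in (1, 2, 3):
            raise ValidationError("degree must be 1, 2 or 3")


@dataclass
class LcmmFit:
    """A converged latent-class mixed model."""

    config: LcmmConfig
    pi: np.ndarray  # (K,)
    beta: np.ndarray  # (K, degree+1)
    tau2: float
    sigma2: float
    loglik: float
    n_params: int
    n_subjects: int
    bic: float
    sabic: float
    posterior_matrix: np.ndarray  # (n, K)
    weeks: np.ndarray  # weeks entering the likelihood
    converged: bool = True
    n_iter: int = 0
    empty_classes: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    def week6_change(self) -> np.ndarray:
        """Fitted mean change from week 0 to week 6 per class."""
        d = self.beta.shape[1]
        x6 = np.array([6.0**j for j in range(d)])
        x0 = np.array([0.0**j for j in range(d)])
        return self.beta @ (x6 - x0)

    def to_json(self, path=None) -> dict:
        out = {
            "n_classes": int(self.n_classes),
            "degree": int(self.config.degree),
            "baseline_corrected": bool(self.config.baseline_corrected),
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "tau2": float(self.tau2),
            "sigma2": float(self.sigma2),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_subjects": int(self.n_subjects),
            "bic": float(self.bic),
            "sabic": float(self.sabic),
            "converged": bool(self.converged),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=2)
        return out


@dataclass(frozen=True)
class ClassAssignment:
    """Modal class per patient: id -> (class index, max posterior)."""

    assignments: dict


def _design(weeks: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(np.asarray(weeks, float), N=degree + 1, increasing=True)


def _fit_weeks(baseline_corrected: bool) -> np.ndarray:
    return np.arange(1, N_WEEKS) if baseline_corrected else np.arange(N_WEEKS)


def _prep(cohort, config) -> np.ndarray:
    """Score matrix restricted to the likelihood weeks, corrected if asked."""
    Y = cohort_matrix(cohort) if not isinstance(cohort, np.ndarray) else cohort
    if np.isnan(Y).any():
        raise ValidationError("cohort must be complete (curate first)")
    if config.baseline_corrected:
        Y = Y - Y[:, :1]
    return Y[:, _fit_weeks(config.baseline_corrected)]


def _class_logdens(Y, X, beta, tau2, sigma2):
    """(n, K) matrix of log N(y_i; X beta_k, tau2 J + sigma2 I)."""
    n, T = Y.shape
    lam1 = sigma2 + T * tau2
    logdet = np.log(lam1) + (T - 1) * np.log(sigma2)
    mu = X @ beta.T  # (T, K)
    out = np.empty((n, len(beta)))
    for k in range(len(beta)):
        r = Y - mu[:, k]  # (n, T)
        s = r.sum(axis=1)
        rr = np.einsum("ij,ij->i", r, r)
        quad = (rr - s**2 / T) / sigma2 + (s**2 / T) / lam1
        out[:, k] = -0.5 * (T * _LOG2PI + logdet + quad)
    return out


def marginal_loglik(pi, beta, tau2, sigma2, Y, weeks, degree=None):
    """Observed-data log-likelihood sum_i log sum_k pi_k N(y_i; X beta_k, V).

    ``Y`` is (n, len(weeks)); the polynomial design is built on ``weeks``.
    """
    pi = np.asarray(pi, float)
    beta = np.atleast_2d(np.asarray(beta, float))
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    Y = np.asarray(Y, float)
    if not np.isfinite(Y).all() or not np.isfinite(beta).all():
        raise ValidationError("non-finite input")
    if degree is None:
        degree = beta.shape[1] - 1
    X = _design(weeks, degree)
    ld = _class_logdens(Y, X, beta, tau2, sigma2)
    return float(logsumexp(ld + np.log(pi), axis=1).sum())


def _em(Y, X, pi, beta, tau2, sigma2, max_iter, rel_tol):
    """Run EM to convergence from one start; returns params, ll, W, n_iter."""
    n, T = Y.shape
    XtX_solve = None
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        # E-step
        ld = _class_logdens(Y, X, beta, tau2, sigma2) + np.log(pi)
        norm = logsumexp(ld, axis=1)
        W = np.exp(ld - norm[:, None])
        ll = float(norm.sum())
        if abs(ll - ll_prev) <= rel_tol * (abs(ll_prev) + 1e-12) and it > 1:
            return (pi, beta, tau2, sigma2), ll, W, it, True
        ll_prev = ll
        # M-step: proportions and GLS coefficients.  With V shared across
        # classes and scalar subject weights, the weighted GLS reduces to a
        # GLS fit of the class-weighted mean profile.
        colsum = W.sum(axis=0)
        pi = np.maximum(colsum / n, 1e-12)
        pi = pi / pi.sum()
        lam1 = sigma2 + T * tau2
        # V^{-1} = (I - P)/sigma2 + P/lam1, P = J/T
        P = np.full((T, T), 1.0 / T)
        Vinv = (np.eye(T) - P) / sigma2 + P / lam1
        A = X.T @ Vinv @ X
        for k in range(beta.shape[0]):
            ybar = (W[:, k] @ Y) / max(colsum[k], 1e-12)
            beta[k] = np.linalg.solve(A, X.T @ Vinv @ ybar)
        # M-step: variance components (closed form via eigenstructure)
        mu = X @ beta.T
        s1 = 0.0
        s2 = 0.0
        for k in range(beta.shape[0]):
            r = Y - mu[:, k]
            s = r.sum(axis=1)
            rr = np.einsum("ij,ij->i", r, r)
            s1 += W[:, k] @ (s**2 / T)
            s2 += W[:, k] @ rr
        s1 /= n
        s2 = s2 / n - s1
        sig_new = s2 / (T - 1)
        if s1 >= sig_new:
            sigma2 = max(sig_new, 1e-10)
            tau2 = max((s1 - sigma2) / T, 0.0)
        else:  # boundary: no between-patient variance
            sigma2 = max((s1 + s2) / T, 1e-10)
            tau2 = 0.0
    # hit max_iter: return best effort, flagged non-converged
    ld = _class_logdens(Y, X, beta, tau2, sigma2) + np.log(pi)
    norm = logsumexp(ld, axis=1)
    return (
        (pi, beta, tau2, sigma2),
        float(norm.sum()),
        np.exp(ld - norm[:, None]),
        max_iter,
        False,
    )


def _init_starts(Y, X, K, degree, n_starts, seed):
    """Yield (pi, beta, tau2, sigma2) initializations: k-means + perturbations."""
    rng = rng_from(seed)
    n, T = Y.shape
    km = KMeans(n_clusters=K, n_init=5, random_state=seed % (2**31)).fit(Y)
    base_labels = km.labels_
    var = Y.var(axis=0).mean()
    for s in range(n_starts):
        labels = base_labels.copy()
        if s > 0:  # perturb: reassign a random 25% of subjects
            idx = rng.choice(n, size=max(1, n // 4), replace=False)
            labels[idx] = rng.integers(0, K, size=idx.size)
        pi = np.array([(labels == k).mean() for k in range(K)])
        pi = np.maximum(pi, 1.0 / n)
        pi /= pi.sum()
        beta = np.empty((K, degree + 1))
        for k in range(K):
            sel = labels == k
            ybar = Y[sel].mean(axis=0) if sel.any() else Y.mean(axis=0)
            beta[k] = np.linalg.lstsq(X, ybar, rcond=None)[0]
        yield pi, beta, max(var * 0.3, 1e-3), max(var * 0.3, 1e-3)


def fit(cohort, config: LcmmConfig) -> LcmmFit:
    """Maximum-likelihood latent-class fit by multi-start EM.

    Starts from a k-means partition of the score vectors plus randomly
    perturbed variants; keeps the best converged log-likelihood.  Classes
    are re-ordered by fitted week-6 mean change (most improvement first).
    """
    K, d = config.n_classes, config.degree
    Y = _prep(cohort, config)
    n, T = Y.shape
    if n < K * (d + 2):
        raise ValidationError(f"need at least {K * (d + 2)} subjects for K={K}, d={d}")
    weeks = _fit_weeks(config.baseline_corrected)
    X = _design(weeks, d)
    best = None
    n_starts = config.n_starts if K > 1 else max(1, min(config.n_starts, 3))
    for init in _init_starts(Y, X, K, d, n_starts, config.seed):
        params, ll, W, n_iter, conv = _em(
            Y, X, *[np.array(v, float) if np.ndim(v) else v for v in init],
            config.max_iter, config.rel_tol,
        )
        # a converged start always beats a non-converged one; otherwise best ll
        key = (conv, ll)
        if best is None or key > (best[4], best[1] + 1e-10):
            best = (params, ll, W, n_iter, conv)
    (pi, beta, tau2, sigma2), ll, W, n_iter, converged = best
    if not converged:
        raise ValidationError(
            f"EM failed to converge in {config.max_iter} iterations "
            f"(best log-likelihood {ll:.4f})"
        )
    # canonical ordering: most week-6 improvement (most negative change) first
    d1 = beta.shape[1]
    x6 = np.array([6.0**j for j in range(d1)])
    x0 = np.array([0.0**j for j in range(d1)])
    change = beta @ (x6 - x0)
    order = np.argsort(change, kind="stable")
    pi, beta, W = pi[order], beta[order], W[:, order]
    p = (K - 1) + K * (d + 1) + 2
    bic = -2 * ll + p * np.log(n)
    sabic = -2 * ll + p * np.log((n + 2) / 24.0)
    empty = [int(k) for k in range(K) if pi[k] < 1.0 / n]
    return LcmmFit(
        config=config,
        pi=pi,
        beta=beta,
        tau2=float(tau2),
        sigma2=float(sigma2),
        loglik=ll,
        n_params=p,
        n_subjects=n,
        bic=float(bic),
        sabic=float(sabic),
        posterior_matrix=W,
        weeks=weeks,
        converged=converged,
        n_iter=n_iter,
        empty_classes=empty,
    )


def information_criteria(fit: LcmmFit) -> tuple[float, float]:
    """(BIC, SABIC): -2l + p ln n and -2l + p ln((n+2)/24), n = subjects."""
    p, n, ll = fit.n_params, fit.n_subjects, fit.loglik
    return -2 * ll + p * np.log(n), -2 * ll + p * np.log((n + 2) / 24.0)


def _observed_for_fit(fit: LcmmFit, series, w: int):
    """Weeks <= w usable under the fit's likelihood, and their (corrected) values.

    ``series`` may be a PatientSeries or a bare 7-vector of raw scores.
    """
    if isinstance(series, PatientSeries):
        y = series.weekly_scores
        corrected = series.baseline_corrected
    else:
        y = np.asarray(series, float)
        corrected = False
    if fit.config.baseline_corrected and not corrected:
        y = y - y[0]
    weeks = [
        t
        for t in range(min(w, 6) + 1)
        if not np.isnan(y[t]) and (t >= 1 or not fit.config.baseline_corrected)
    ]
    return np.array(weeks, dtype=float), y[weeks] if weeks else np.array([])


def posterior(fit: LcmmFit, series, w: int = 6) -> np.ndarray:
    """Class posterior from weeks 0..w of one series, by Bayes' rule.

    ``series`` may be a PatientSeries or a bare 7-vector of raw scores.
    Only weeks that enter the fit's likelihood are used (baseline-corrected
    fits ignore the structurally-zero week 0); with no informative weeks the
    prior pi is returned.
    """
    if w > 6 or w < 0:
        raise ValidationError("w must be in 0..6")
    if fit.n_classes == 1:
        return np.array([1.0])
    weeks, yobs = _observed_for_fit(fit, series, w)
    if weeks.size == 0:
        return fit.pi.copy()
    X = _design(weeks, fit.config.degree)
    ld = _class_logdens(yobs[None, :], X, fit.beta, fit.tau2, fit.sigma2)[0]
    lw = ld + np.log(fit.pi)
    return np.exp(lw - logsumexp(lw))


def empirical_bayes_intercept(
    fit: LcmmFit, series: PatientSeries, w: int, k: int
) -> float:
    """BLUP of the random intercept given class k and weeks 0..w.

    tau^2 1' V^{-1} (y - X beta_k) over the observed weeks; identically 0
    when tau^2 = 0.
    """
    if fit.tau2 == 0.0:
        return 0.0
    weeks, yobs = _observed_for_fit(fit, series, w)
    if weeks.size == 0:
        return 0.0
    T = weeks.size
    X = _design(weeks, fit.config.degree)
    r = yobs - X @ fit.beta[k]
    # 1' V^{-1} r with V = tau2 J + sigma2 I: every row sum of V^{-1} equals
    # 1 / (sigma2 + T tau2)
    return float(fit.tau2 * r.sum() / (fit.sigma2 + T * fit.tau2))


def assign_classes(fit: LcmmFit, cohort=None) -> ClassAssignment:
    """Modal class per patient (argmax posterior; ties to the lower index)."""
    W = fit.posterior_matrix
    ids = (
        [s.patient_id for s in cohort]
        if cohort is not None
        else [str(i) for i in range(W.shape[0])]
    )
    out = {}
    for pid, row in zip(ids, W):
        k = int(np.argmax(row))  # argmax takes the first (better-improving) on ties
        out[pid] = (k, float(row[k]))
    return ClassAssignment(assignments=out)


def class_curves(fit: LcmmFit, weeks=None) -> np.ndarray:
    """(K, len(weeks)) fitted class mean curves on the fit's score scale."""
    if weeks is None:
        weeks = np.arange(N_WEEKS)
    X = _design(np.asarray(weeks, float), fit.config.degree)
    return fit.beta @ X.T
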