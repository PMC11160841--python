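"""Exponential-decay nonlinear mixed-effects model of the treatment course.

The mean model for patient i at week t is

    y_it = Change_i * exp(-t / B_i) + End_i + e_it,

a total modeled reduction ``Change`` that decays with time constant ``B``
(weeks) toward an asymptotic end score ``End``.  Any subset of the three
parameters can carry patient-level random effects; B is handled on the log
scale internally so the time constant stays positive.

Estimation alternates, Lindstrom-Bates style, between (a) penalized
nonlinear least squares for the per-patient random-effect modes (a damped
Gauss-Newton vectorized across the cohort) and (b) fixed-effect and
variance-component updates on the model linearized at the current modes.
The reported log-likelihood is the Laplace approximation to the marginal
likelihood at the converged estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._utils import N_WEEKS, ValidationError
from .curation import cohort_matrix

__all__ = [
    "DecayParams",
    "DecayFit",
    "decay_curve",
    "fit_nlme",
    "compare_random_effects",
]

_LOG2PI = np.log(2.0 * np.pi)
_PARAM_NAMES = ("change", "b", "end")


@dataclass(frozen=True)
class DecayParams:
    """Population or per-patient decay parameters (points, weeks, points)."""

    change: float
    b: float
    end: float

    def __post_init__(self):
        if self.b <= 0:
            raise ValidationError("time constant B must be positive")


def decay_curve(t, params: DecayParams):
    """Model value Change * exp(-t / B) + End at week(s) t >= 0."""
    t = np.asarray(t, float)
    if (t < 0).any():
        raise ValidationError("t must be >= 0")
    return params.change * np.exp(-t / params.b) + params.end


def _f_and_jac(theta, t):
    """Mean curves and Jacobians for internal params (C, log B, E).

    theta: (n, 3); returns f (n, T) and J (n, T, 3).
    """
    C, logB, E = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
    B = np.exp(logB)
    ex = np.exp(-t[None, :] / B)  # (n, T)
    f = C * ex + E
    J = np.empty((theta.shape[0], t.size, 3))
    J[:, :, 0] = ex
    J[:, :, 1] = C * ex * (t[None, :] / B)  # d/d logB
    J[:, :, 2] = 1.0
    return f, J


def _pnls(Y, t, beta, S, psi_inv, sigma2, eta, n_iter=50, tol=1e-10):
    """Per-patient penalized Gauss-Newton, vectorized across the cohort.

    Minimizes ||y_i - f(beta + S eta_i)||^2 / sigma2 + eta_i' psi_inv eta_i
    for every patient simultaneously, with per-patient Levenberg damping.
    """
    n = Y.shape[0]
    q = S.shape[1]
    lam = np.full(n, 1e-4)

    def objective(eta):
        theta = beta[None, :] + eta @ S.T
        f, _ = _f_and_jac(theta, t)
        r = Y - f
        return (r**2).sum(axis=1) / sigma2 + np.einsum(
            "iq,qp,ip->i", eta, psi_inv, eta
        )

    obj = objective(eta)
    for _ in range(n_iter):
        theta = beta[None, :] + eta @ S.T
        f, Jfull = _f_and_jac(theta, t)
        r = Y - f  # (n, T)
        J = Jfull @ S  # (n, T, q)
        g = np.einsum("itq,it->iq", J, r) / sigma2 - eta @ psi_inv.T
        H = np.einsum("itq,itp->iqp", J, J) / sigma2 + psi_inv[None, :, :]
        step_ok = np.zeros(n, bool)
        new_eta = eta.copy()
        for _damp in range(8):
            act = ~step_ok
            if not act.any():
                break
            Hd = H[act] + lam[act][:, None, None] * np.eye(q)[None]
            try:
                delta = np.linalg.solve(Hd, g[act][..., None])[..., 0]
            except np.linalg.LinAlgError:
                lam[act] *= 10
                continue
            cand = eta[act] + delta
            trial = new_eta.copy()
            trial[act] = cand
            obj_t = objective(trial)
            improved = obj_t[act] <= obj[act] + 1e-12
            idx = np.flatnonzero(act)
            good, bad = idx[improved], idx[~improved]
            new_eta[good] = trial[good]
            lam[good] = np.maximum(lam[good] * 0.3, 1e-8)
            lam[bad] *= 10
            step_ok[good] = True
        new_obj = objective(new_eta)
        if np.max(np.abs(new_obj - obj)) < tol * (1 + np.abs(obj).max()):
            eta, obj = new_eta, new_obj
            break
        eta, obj = new_eta, new_obj
    return eta


def _laplace_loglik(Y, t, beta, S, psi, psi_inv, sigma2, eta):
    n, T = Y.shape
    q = S.shape[1]
    theta = beta[None, :] + eta @ S.T
    f, Jfull = _f_and_jac(theta, t)
    r = Y - f
    rss = (r**2).sum(axis=1)
    pen = np.einsum("iq,qp,ip->i", eta, psi_inv, eta)
    J = Jfull @ S
    H = np.einsum("itq,itp->iqp", J, J) / sigma2 + psi_inv[None, :, :]
    sign, logdet_h = np.linalg.slogdet(H)
    _, logdet_psi = np.linalg.slogdet(psi)
    ll = -0.5 * (
        rss / sigma2 + pen + T * np.log(2 * np.pi * sigma2) + logdet_psi + logdet_h
    )
    return float(ll.sum())


@dataclass
class DecayFit:
    """A fitted exponential-decay NLME."""

    params: DecayParams
    psi: np.ndarray | None  # random-effect covariance on (change, log B, end) subscale
    sigma2: float
    loglik: float
    aic: float
    bic: float
    n_params: int
    n_subjects: int
    random_effects: tuple
    ranef: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True
    n_iter: int = 0

    def to_json(self, path=None) -> dict:
        out = {
            "change": self.params.change,
            "b": self.params.b,
            "end": self.params.end,
            "psi": None if self.psi is None else self.psi.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_params": self.n_params,
            "random_effects": list(self.random_effects),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=2)
        return out


def _init_beta(Y, t):
    """Pooled nonlinear least squares on the cohort mean profile."""
    ybar = Y.mean(axis=0)
    end0 = max(ybar[-1], 0.5)
    change0 = max(ybar[0] - ybar[-1], 0.5)

    def resid(p):
        C, logB, E = p
        return C * np.exp(-t / np.exp(logB)) + E - ybar

    sol = least_squares(resid, x0=[change0, np.log(2.0), end0], method="lm")
    return sol.x


def fit_nlme(
    cohort,
    random_effects=("change", "b", "end"),
    max_iter: int = 200,
    rel_tol: float = 1e-6,
    verbose: bool = False,
) -> DecayFit:
    """Fit the decay NLME with the requested random-effect structure.

    ``random_effects`` is a subset of {"change", "b", "end"}; an empty
    subset falls back to plain pooled nonlinear least squares.  Requires at
    least 20 complete subjects.
    """
    Y = cohort_matrix(cohort) if not isinstance(cohort, np.ndarray) else cohort
    if np.isnan(Y).any():
        raise ValidationError("cohort must be complete (curate first)")
    n, T = Y.shape
    t = np.arange(T, dtype=float)
    random_effects = tuple(random_effects)
    for nm in random_effects:
        if nm not in _PARAM_NAMES:
            raise ValidationError(f"unknown random effect {nm!r}")
    q = len(random_effects)
    beta = _init_beta(Y, t)

    if q == 0:
        def resid(p):
            C, logB, E = p
            return (C * np.exp(-t[None, :] / np.exp(logB)) + E - Y).ravel()

        sol = least_squares(resid, x0=beta, method="lm")
        rss = float((sol.fun**2).sum())
        sigma2 = rss / (n * T)
        ll = -0.5 * (n * T * np.log(2 * np.pi * sigma2) + rss / sigma2)
        p = 4
        return DecayFit(
            params=DecayParams(sol.x[0], float(np.exp(sol.x[1])), sol.x[2]),
            psi=None,
            sigma2=sigma2,
            loglik=ll,
            aic=-2 * ll + 2 * p,
            bic=-2 * ll + p * np.log(n),
            n_params=p,
            n_subjects=n,
            random_effects=(),
        )

    if n < 20:
        raise ValidationError("need at least 20 subjects for a mixed fit")
    S = np.zeros((3, q))
    for j, nm in enumerate(random_effects):
        S[_PARAM_NAMES.index(nm), j] = 1.0

    # crude starting variances from per-patient moment summaries
    chg = Y[:, 0] - Y[:, -1]
    start_var = {"change": max(np.var(chg) * 0.5, 0.1), "b": 0.05,
                 "end": max(np.var(Y[:, -1]) * 0.5, 0.1)}
    psi = np.diag([start_var[nm] for nm in random_effects])
    f0, _ = _f_and_jac(beta[None, :], t)
    sigma2 = max(float(np.var(Y - f0)), 1e-4)
    eta = np.zeros((n, q))
    psi_floor = 1e-8 * max(float(Y.var()), 1.0)
    psi_inv = np.linalg.inv(psi + 1e-10 * np.eye(q))
    eta = _pnls(Y, t, beta, S, psi_inv, sigma2, eta)
    ll = _laplace_loglik(Y, t, beta, S, psi, psi_inv, sigma2, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # LME proposal: one EM sweep on the model linearized at the modes
        theta = beta[None, :] + eta @ S.T
        f, Jfull = _f_and_jac(theta, t)
        Z = Jfull @ S  # (n, T, q)
        w = Y - f + np.einsum("itp,p->it", Jfull, beta) + np.einsum(
            "itq,iq->it", Z, eta
        )
        V = np.einsum("itq,qp,isp->its", Z, psi, Z) + sigma2 * np.eye(T)[None]
        Vinv = np.linalg.inv(V)
        A = Jfull
        lhs = np.einsum("itp,its,isr->pr", A, Vinv, A)
        rhs = np.einsum("itp,its,is->p", A, Vinv, w)
        # lstsq guards against the near-singular design that arises when
        # B grows large and exp(-t/B) becomes collinear with the intercept
        beta_prop = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        beta_prop[1] = np.clip(beta_prop[1], -3.0, 4.0)  # B in ~[0.05, 55] weeks
        resid = w - np.einsum("itp,p->it", A, beta_prop)
        K = np.einsum("qp,itp,its->iqs", psi, Z, Vinv)  # psi Z' V^{-1}
        eta_t = np.einsum("iqs,is->iq", K, resid)
        cov_t = psi[None] - np.einsum("iqt,itp,pr->iqr", K, Z, psi)
        cov_t = 0.5 * (cov_t + np.swapaxes(cov_t, 1, 2))
        psi_prop = (np.einsum("iq,ip->qp", eta_t, eta_t) + cov_t.sum(axis=0)) / n
        psi_prop = 0.5 * (psi_prop + psi_prop.T)
        # pin variance components collapsing to zero at a small floor: EM
        # otherwise approaches the boundary at a crawl and never converges
        small = np.flatnonzero(psi_prop.diagonal() < psi_floor)
        if small.size:
            psi_prop[small, :] = 0.0
            psi_prop[:, small] = 0.0
            psi_prop[small, small] = psi_floor
        fit_res = resid - np.einsum("itq,iq->it", Z, eta_t)
        tr = np.einsum("itq,iqp,itp->", Z, cov_t, Z)
        sig_prop = max(float(((fit_res**2).sum() + tr) / (n * T)), 1e-8)
        # step-halving against the Laplace log-likelihood keeps the outer
        # iteration monotone even when the linearization overshoots
        step = 1.0
        accepted = False
        for _half in range(8):
            beta_t = beta + step * (beta_prop - beta)
            psi_t = psi + step * (psi_prop - psi)  # convex mix of PSD matrices
            sig_t = sigma2 + step * (sig_prop - sigma2)
            psi_inv_t = np.linalg.inv(psi_t + 1e-10 * np.eye(q))
            eta_new = _pnls(Y, t, beta_t, S, psi_inv_t, sig_t, eta)
            ll_new = _laplace_loglik(Y, t, beta_t, S, psi_t, psi_inv_t, sig_t, eta_new)
            if ll_new >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if verbose:
            print(f"iter {it}: ll = {ll_new:.6f} (step {step})")
        improved = ll_new - ll
        if accepted:
            beta, psi, sigma2, eta, ll = beta_t, psi_t, sig_t, eta_new, ll_new
        if (accepted and abs(improved) <= rel_tol * (abs(ll) + 1e-12)) or not accepted:
            converged = True
            break
    if not converged and max_iter > 1:
        raise ValidationError(
            f"NLME failed to converge in {max_iter} iterations (last ll {ll:.4f})"
        )
    psi_inv = np.linalg.inv(psi + 1e-10 * np.eye(q))
    eta = _pnls(Y, t, beta, S, psi_inv, sigma2, eta)
    ll = _laplace_loglik(Y, t, beta, S, psi, psi_inv, sigma2, eta)
    theta = beta[None, :] + eta @ S.T
    ranef = pd.DataFrame(
        {
            "patient_id": [getattr(s, "patient_id", str(i)) for i, s in enumerate(cohort)]
            if not isinstance(cohort, np.ndarray)
            else [str(i) for i in range(n)],
            "change": theta[:, 0],
            "b": np.exp(theta[:, 1]),
            "end": theta[:, 2],
        }
    )
    p = 3 + q * (q + 1) // 2 + 1
    return DecayFit(
        params=DecayParams(float(beta[0]), float(np.exp(beta[1])), float(beta[2])),
        psi=psi,
        sigma2=float(sigma2),
        loglik=ll,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * np.log(n),
        n_params=p,
        n_subjects=n,
        random_effects=random_effects,
        ranef=ranef,
        converged=converged,
        n_iter=it,
    )


def compare_random_effects(fit_full: DecayFit, fit_reduced: DecayFit) -> dict:
    """Likelihood-ratio and information-criterion comparison of nested fits.

    The LRT here is the model-preference heuristic used in practice for
    random-effect structures; the boundary-of-parameter-space caveat (true
    null distribution is a chi-square mixture) is documented, not corrected.
    """
    if fit_full.n_subjects != fit_reduced.n_subjects:
        raise ValidationError("fits must come from the same cohort")
    if not set(fit_reduced.random_effects) <= set(fit_full.random_effects):
        raise ValidationError("random-effect structures are not nested")
    lrt = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    df = fit_full.n_params - fit_reduced.n_params
    d_aic = fit_reduced.aic - fit_full.aic
    d_bic = fit_reduced.bic - fit_full.bic
    return {
        "lrt": lrt,
        "df": df,
        "delta_aic": d_aic,
        "delta_bic": d_bic,
        "aic_prefers": "full" if d_aic > 0 else "reduced",
        "bic_prefers": "full" if d_bic > 0 else "reduced",
    }
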