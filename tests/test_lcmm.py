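"""Latent-class mixed model: likelihood, EM fit, posteriors, BLUPs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmstraj.lcmm import (
    LcmmConfig,
    LcmmFit,
    assign_classes,
    class_curves,
    empirical_bayes_intercept,
    fit,
    information_criteria,
    marginal_loglik,
    posterior,
)
from tmstraj.simulate import LcmmSimSpec, simulate_lcmm_cohort

from conftest import make_series


def toy_fit(pi, beta, tau2, sigma2, baseline_corrected=False):
    beta = np.atleast_2d(np.asarray(beta, float))
    pi = np.asarray(pi, float)
    cfg = LcmmConfig(
        n_classes=len(pi), degree=beta.shape[1] - 1,
        baseline_corrected=baseline_corrected, seed=0,
    )
    weeks = np.arange(1, 7) if baseline_corrected else np.arange(7)
    K = len(pi)
    return LcmmFit(
        config=cfg, pi=pi, beta=beta, tau2=tau2, sigma2=sigma2, loglik=0.0,
        n_params=0, n_subjects=1, bic=0.0, sabic=0.0,
        posterior_matrix=np.full((1, K), 1.0 / K), weeks=weeks,
    )


class TestMarginalLoglik:
    def test_single_class_matches_mvn_density(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(5, 20, size=(3, 7))
        beta = np.array([[17.0, -1.0]])
        tau2, sigma2 = 2.0, 1.5
        weeks = np.arange(7)
        X = np.vander(weeks.astype(float), N=2, increasing=True)
        V = tau2 * np.ones((7, 7)) + sigma2 * np.eye(7)
        expect = sum(
            stats.multivariate_normal.logpdf(y, X @ beta[0], V) for y in Y
        )
        got = marginal_loglik([1.0], beta, tau2, sigma2, Y, weeks)
        assert np.isclose(got, expect, atol=1e-8)

    def test_tau_zero_reduces_to_iid_normal(self):
        rng = np.random.default_rng(1)
        Y = rng.uniform(5, 20, size=(4, 7))
        beta = np.array([[15.0, -0.5]])
        sigma2 = 2.0
        weeks = np.arange(7)
        X = np.vander(weeks.astype(float), N=2, increasing=True)
        resid = Y - X @ beta[0]
        expect = stats.norm.logpdf(resid, scale=np.sqrt(sigma2)).sum()
        got = marginal_loglik([1.0], beta, 0.0, sigma2, Y, weeks)
        assert np.isclose(got, expect, atol=1e-8)

    def test_duplicating_patients_doubles_loglik(self):
        rng = np.random.default_rng(2)
        Y = rng.uniform(5, 20, size=(3, 7))
        args = ([0.4, 0.6], [[17, -1], [17, 0]], 1.0, 1.0)
        one = marginal_loglik(*args, Y, np.arange(7))
        two = marginal_loglik(*args, np.vstack([Y, Y]), np.arange(7))
        assert np.isclose(two, 2 * one, atol=1e-8)

    def test_rejects_bad_inputs(self):
        from tmstraj import ValidationError

        Y = np.ones((2, 7))
        with pytest.raises(ValidationError):
            marginal_loglik([1.0], [[1, 0]], 1.0, 0.0, Y, np.arange(7))
        with pytest.raises(ValidationError):
            marginal_loglik([1.0], [[np.inf, 0]], 1.0, 1.0, Y, np.arange(7))


class TestFit:
    def test_single_class_linear_recovery(self):
        spec = LcmmSimSpec(
            n_patients=200, class_proportions=(1.0,),
            class_coefficients=((17.0, -1.0, 0.0, 0.0),),
            tau=0.5, sigma=0.5, seed=11,
        )
        cohort, _, _ = simulate_lcmm_cohort(spec)
        f = fit(cohort, LcmmConfig(1, 1, baseline_corrected=False, seed=1))
        assert np.allclose(f.beta[0], [17.0, -1.0], atol=0.1)

    def test_refit_reproduces_loglik(self, lcmm_cohort):
        cohort, _, _ = lcmm_cohort
        cfg = LcmmConfig(2, 3, baseline_corrected=True, n_starts=4, seed=42)
        assert abs(fit(cohort, cfg).loglik - fit(cohort, cfg).loglik) < 1e-8

    def test_loglik_nondecreasing_in_k(self, lcmm_cohort):
        cohort, _, _ = lcmm_cohort
        ll = [
            fit(
                cohort,
                LcmmConfig(K, 3, baseline_corrected=True, n_starts=6, seed=3),
            ).loglik
            for K in (1, 2)
        ]
        assert ll[1] >= ll[0] - 1e-6

    def test_posterior_rows_sum_to_one(self, lcmm_fit_default):
        rowsums = lcmm_fit_default.posterior_matrix.sum(axis=1)
        assert np.allclose(rowsums, 1.0, atol=1e-10)

    def test_baseline_corrected_drops_week0(self, lcmm_fit_default):
        assert np.array_equal(lcmm_fit_default.weeks, np.arange(1, 7))

    def test_canonical_order_most_improving_first(self, lcmm_fit_default):
        change = lcmm_fit_default.week6_change()
        assert change[0] <= change[1]


class TestInformationCriteria:
    def test_unit_penalty_argument(self):
        f = toy_fit([1.0], [[0, 0]], 1.0, 1.0)
        f.loglik, f.n_params, f.n_subjects = -100.0, 5, 22
        bic, sabic = information_criteria(f)
        assert np.isclose(sabic, 200.0)

    def test_single_subject_bic(self):
        f = toy_fit([1.0], [[0, 0]], 1.0, 1.0)
        f.loglik, f.n_params, f.n_subjects = -100.0, 5, 1
        bic, _ = information_criteria(f)
        assert np.isclose(bic, 200.0)

    def test_sabic_below_bic_for_large_n(self):
        f = toy_fit([1.0], [[0, 0]], 1.0, 1.0)
        f.loglik, f.n_params, f.n_subjects = -100.0, 5, 100
        bic, sabic = information_criteria(f)
        assert sabic < bic


class TestPosterior:
    def test_single_class(self):
        f = toy_fit([1.0], [[17, -1]], 1.0, 1.0)
        s = make_series([17, 16, 15, 14, 13, 12, 11])
        assert np.array_equal(posterior(f, s, 6), [1.0])

    def test_symmetric_equidistant_series(self):
        f = toy_fit([0.5, 0.5], [[16, -1], [16, 1]], 1.0, 1.0)
        s = make_series([16.0] * 7)
        assert np.allclose(posterior(f, s, 6), [0.5, 0.5], atol=1e-12)

    def test_matches_brute_force_bayes(self):
        """Two observed weeks, hand-evaluated normal densities."""
        f = toy_fit([0.3, 0.7], [[17, -2], [17, 0]], tau2=2.0, sigma2=1.0)
        scores = np.full(7, np.nan)
        scores[0], scores[1] = 16.0, 13.0
        s = make_series(scores)
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        V = 2.0 * np.ones((2, 2)) + 1.0 * np.eye(2)
        y = np.array([16.0, 13.0])
        dens = np.array(
            [stats.multivariate_normal.pdf(y, X @ b, V) for b in f.beta]
        )
        expect = np.array([0.3, 0.7]) * dens
        expect /= expect.sum()
        assert np.allclose(posterior(f, s, 1), expect, atol=1e-12)

    def test_prior_returned_without_informative_weeks(self):
        f = toy_fit([0.3, 0.7], [[0, -2], [0, 0]], 1.0, 1.0, baseline_corrected=True)
        s = make_series([15.0] + [np.nan] * 6)
        assert np.allclose(posterior(f, s, 0), [0.3, 0.7])

    @given(
        scores=st.lists(
            st.floats(min_value=0, max_value=27, allow_nan=False),
            min_size=7, max_size=7,
        ),
        w=st.integers(min_value=0, max_value=6),
    )
    @settings(max_examples=30, deadline=None)
    def test_normalized_for_any_series(self, scores, w):
        f = toy_fit([0.25, 0.75], [[17, -2], [17, 0]], 1.5, 1.0)
        p = posterior(f, make_series(scores), w)
        assert np.isclose(p.sum(), 1.0, atol=1e-10)
        assert (p >= 0).all()


class TestEmpiricalBayes:
    def test_zero_variance_gives_zero(self):
        f = toy_fit([1.0], [[17, -1]], 0.0, 1.0)
        s = make_series([20, 19, 18, 17, 16, 15, 14])
        assert empirical_bayes_intercept(f, s, 6, 0) == 0.0

    def test_single_week_shrinkage(self):
        tau2, sigma2 = 2.0, 1.0
        f = toy_fit([1.0], [[17, -1]], tau2, sigma2)
        scores = np.full(7, np.nan)
        scores[0] = 20.0  # residual r = 3 at week 0
        got = empirical_bayes_intercept(f, make_series(scores), 0, 0)
        assert np.isclose(got, tau2 * 3.0 / (tau2 + sigma2), atol=1e-12)

    def test_multiweek_matches_matrix_formula(self):
        tau2, sigma2 = 1.3, 0.8
        f = toy_fit([1.0], [[17, -1]], tau2, sigma2)
        s = make_series([19, 17.5, 16, 15, 14, 13, 12])
        w = 3
        X = np.vander(np.arange(4.0), N=2, increasing=True)
        V = tau2 * np.ones((4, 4)) + sigma2 * np.eye(4)
        r = s.weekly_scores[:4] - X @ f.beta[0]
        expect = tau2 * np.ones(4) @ np.linalg.solve(V, r)
        assert np.isclose(empirical_bayes_intercept(f, s, w, 0), expect, atol=1e-10)


class TestAssignClasses:
    def test_argmax_and_tiebreak(self):
        f = toy_fit([0.5, 0.5], [[17, -2], [17, 0]], 1.0, 1.0)
        f.posterior_matrix = np.array([[0.9, 0.1], [0.5, 0.5]])
        a = assign_classes(f).assignments
        assert a["0"] == (0, 0.9)
        assert a["1"][0] == 0  # tie goes to the better-improving class

    def test_matches_rowwise_argmax(self, lcmm_fit_default, lcmm_cohort):
        cohort, _, _ = lcmm_cohort
        a = assign_classes(lcmm_fit_default, cohort).assignments
        W = lcmm_fit_default.posterior_matrix
        for i, s in enumerate(cohort):
            assert a[s.patient_id][0] == int(np.argmax(W[i]))
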