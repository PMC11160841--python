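"""Folds, classification metrics, bootstrap CIs, selection and the experiment."""

import numpy as np
import pytest

from tmstraj import ValidationError
from tmstraj.evaluate import (
    auc_binary,
    bootstrap_ci,
    confusion_metrics,
    make_folds,
    prediction_experiment,
    score_correlation,
    select_lcmm,
)


class TestMakeFolds:
    def test_perfect_stratification(self):
        labels = {f"p{i}": int(i < 5) for i in range(10)}
        plan = make_folds(labels, k=5, seed=1)
        for f in range(5):
            ids = plan.fold_ids(f)
            assert len(ids) == 2
            assert sum(labels[i] for i in ids) == 1

    def test_deterministic_under_seed(self):
        labels = {f"p{i}": i % 3 for i in range(50)}
        a = make_folds(labels, k=5, seed=9)
        b = make_folds(labels, k=5, seed=9)
        assert a.assignment == b.assignment

    def test_fold_sizes_and_proportions(self):
        rng = np.random.default_rng(3)
        labels = {f"p{i}": int(rng.random() < 0.41) for i in range(238)}
        plan = make_folds(labels, k=5, seed=4)
        sizes = [len(plan.fold_ids(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        overall = np.mean(list(labels.values()))
        for f in range(5):
            ids = plan.fold_ids(f)
            prop = np.mean([labels[i] for i in ids])
            assert abs(prop - overall) <= 1.0 / len(ids) + 1e-12

    def test_small_stratum_logged(self):
        labels = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0, "f": 1}
        plan = make_folds(labels, k=3, seed=5)
        assert any("plain randomization" in n for n in plan.notes)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            make_folds({"a": 0}, k=5, seed=0)


class TestConfusionAndAuc:
    def test_all_correct(self):
        p = o = np.array([True, True, False, False])
        assert confusion_metrics(p, o) == (1.0, 1.0)

    def test_predict_all_negative(self):
        o = np.array([True, False, True, False])
        p = np.zeros(4, bool)
        sens, spec = confusion_metrics(p, o)
        assert (sens, spec) == (0.0, 1.0)
        assert auc_binary(p, o) == 0.5

    def test_counting_example(self):
        o = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        p = np.r_[np.ones(44, bool), np.zeros(56, bool),
                  np.ones(5, bool), np.zeros(95, bool)]
        sens, spec = confusion_metrics(p, o)
        assert np.isclose(sens, 0.44) and np.isclose(spec, 0.95)
        assert np.isclose(auc_binary(p, o), 0.695)

    def test_single_class_observed_gives_nan(self):
        o = np.ones(5, bool)
        sens, spec = confusion_metrics(np.ones(5, bool), o)
        assert sens == 1.0 and np.isnan(spec)
        assert np.isnan(auc_binary(np.ones(5, bool), o))


class TestBootstrapCi:
    def test_perfect_separation_zero_width(self):
        o = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        lo, hi = bootstrap_ci(o.copy(), o, "auc", n_boot=200, seed=1)
        assert lo == hi == 1.0

    def test_bounds_within_unit_interval(self):
        rng = np.random.default_rng(2)
        o = rng.random(60) < 0.4
        p = o ^ (rng.random(60) < 0.25)
        for metric in ("auc", "sensitivity", "specificity"):
            lo, hi = bootstrap_ci(p, o, metric, n_boot=500, seed=3)
            assert 0.0 <= lo <= hi <= 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        o = rng.random(80) < 0.5
        p = o ^ (rng.random(80) < 0.2)
        a = bootstrap_ci(p, o, "auc", n_boot=300, seed=7)
        assert a == bootstrap_ci(p, o, "auc", n_boot=300, seed=7)

    def test_callable_metric_agrees_with_named(self):
        rng = np.random.default_rng(5)
        o = rng.random(50) < 0.5
        p = o ^ (rng.random(50) < 0.2)
        named = bootstrap_ci(p, o, "auc", n_boot=400, seed=8)
        loop = bootstrap_ci(p, o, auc_binary, n_boot=400, seed=8)
        assert abs(named[0] - loop[0]) < 0.08 and abs(named[1] - loop[1]) < 0.08


class TestScoreCorrelation:
    def test_identity_and_affine(self):
        x = np.array([3.0, 7.0, 1.0, 9.0, 5.0])
        assert np.isclose(score_correlation(x, x)[0], 1.0)
        assert np.isclose(score_correlation(2 * x + 1, x)[0], 1.0)

    def test_textbook_five_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, (lo, hi) = score_correlation(x, y)
        expect = np.corrcoef(x, y)[0, 1]
        assert np.isclose(r, expect, atol=1e-12)
        assert lo < r < hi

    def test_zero_variance_is_missing(self):
        r, ci = score_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(r)


@pytest.fixture(scope="module")
def selection(lcmm_cohort):
    cohort, _, _ = lcmm_cohort
    return select_lcmm(
        cohort, n_classes_grid=(1, 2, 3), degree_grid=(2, 3),
        modes=(True,), k=5, seed=5, n_starts=4,
    )


@pytest.fixture(scope="module")
def report(lcmm_cohort):
    cohort, _, _ = lcmm_cohort
    return prediction_experiment(cohort, "lcmm-bc", seed=9, n_boot=200, n_starts=4)


class TestSelectLcmm:
    def test_delta_sign_convention(self, selection):
        """Delta = simpler minus more complex; positive favors complexity."""
        table, _ = selection
        for _, row in table.iterrows():
            simpler = table[
                (table.degree == row.degree)
                & (table.n_classes == row.n_classes - 1)
            ]
            if len(simpler):
                assert np.isclose(
                    row.delta_bic_class, simpler.iloc[0].bic - row.bic, atol=1e-9
                )

    def test_single_class_full_share(self, selection):
        table, _ = selection
        ones = table[table.n_classes == 1]
        assert (ones.min_class_share == 100.0).all()

    def test_chosen_recovers_two_classes(self, selection):
        # the generating cubic terms are mild, so BIC may settle on LQ or
        # LQC; the class count is the recoverable quantity
        _, chosen = selection
        assert chosen["n_classes"] == 2


class TestPredictionExperiment:
    def test_report_shape(self, report):
        for rd in ("fifty_percent", "improvement_class"):
            sub = report.rows[report.rows.response_def == rd]
            assert sorted(sub.w) == list(range(7))

    def test_fold_average_consistency(self, report):
        """Fold-averaged AUC equals (avg sensitivity + avg specificity)/2."""
        got = report.rows
        assert np.allclose(
            got.auc, (got.sensitivity + got.specificity) / 2.0, atol=1e-12
        )

    def test_near_oracle_limit_on_well_separated_cohort(self):
        """Deep separation and full data: AUC >= 0.95 for both definitions."""
        from tmstraj.simulate import LcmmSimSpec, simulate_lcmm_cohort

        spec = LcmmSimSpec(
            n_patients=240,
            class_proportions=(0.5, 0.5),
            class_coefficients=(
                (17.86, -3.0, 0.12, -0.32 / 216.0),   # ~14-point reduction
                (17.86, -0.12, 0.012, 0.0),           # near flat
            ),
            tau=3.0, sigma=0.8, seed=77,
        )
        cohort, _, _ = simulate_lcmm_cohort(spec)
        rep = prediction_experiment(cohort, "lcmm-bc", seed=6, n_boot=200, n_starts=4)
        sub = rep.rows[rep.rows.w == 6]
        assert (sub.auc >= 0.95).all()

    def test_auc_improves_with_information(self, report):
        sub = report.rows[report.rows.response_def == "improvement_class"]
        assert sub[sub.w == 6].auc.iloc[0] > sub[sub.w == 0].auc.iloc[0]

    def test_unknown_model_rejected(self, lcmm_cohort):
        cohort, _, _ = lcmm_cohort
        with pytest.raises(ValidationError):
            prediction_experiment(cohort, "nope", seed=1)

    def test_small_cohort_rejected(self, lcmm_cohort):
        cohort, _, _ = lcmm_cohort
        with pytest.raises(ValidationError):
            prediction_experiment(cohort[:30], "lcmm-bc", seed=1)
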