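import numpy as np
import pandas as pd
import pytest

from neurofuse.cohort import generate_cohort
from neurofuse.crossval import (
    ClassifierSpec,
    accuracy_summary,
    cross_validate_unimodal,
    fit_predict_fold,
    labels_from_probs,
    make_folds,
)
from neurofuse.errors import ConfigurationError

from conftest import small_spec


def reference_labels(n_controls=115, n_patients=96):
    return np.concatenate([np.zeros(n_controls, np.int64), np.ones(n_patients, np.int64)])


class TestMakeFolds:
    def test_reference_cohort_fold_sizes(self):
        labels = reference_labels()
        plan = make_folds(labels, n_folds=10, seed=0)
        sizes = [len(plan.test_indices(f)) for f in range(10)]
        assert sum(sizes) == 211
        assert set(sizes) <= {21, 22}
        for f in range(10):
            controls = np.sum(labels[plan.test_indices(f)] == 0)
            assert controls in (11, 12)

    def test_same_seed_identical(self):
        labels = reference_labels()
        a = make_folds(labels, 10, seed=3)
        b = make_folds(labels, 10, seed=3)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_leave_one_out(self):
        labels = np.array([0, 1] * 10)
        plan = make_folds(labels, n_folds=20, seed=0, stratified=False)
        assert sorted(len(plan.test_indices(f)) for f in range(20)) == [1] * 20

    def test_small_class_rejected(self):
        labels = np.array([0] * 30 + [1] * 5)
        with pytest.raises(ConfigurationError):
            make_folds(labels, n_folds=10, seed=0, stratified=True)

    def test_every_subject_once(self):
        labels = reference_labels()
        plan = make_folds(labels, 10, seed=1)
        assert np.all(plan.assignment >= 0)
        assert np.all(np.bincount(plan.assignment) > 0)


class TestFitPredictFold:
    def _separable(self, n=60, v=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        x = rng.normal(size=(n, v)) * 0.01 + y[:, None] * 5.0
        return x, y

    @pytest.mark.parametrize("family", ["ridge", "lasso", "random_forest", "gradient_boosting"])
    def test_separable_perfect(self, family, fast_ridge, fast_lasso, fast_forest, fast_boost):
        spec = {
            "ridge": fast_ridge,
            "lasso": fast_lasso,
            "random_forest": fast_forest,
            "gradient_boosting": fast_boost,
        }[family]
        x, y = self._separable()
        probs = fit_predict_fold(x[:40], y[:40], x[40:], spec)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.array_equal(labels_from_probs(probs), y[40:])

    def test_ridge_infinite_penalty_constant(self):
        # a vanishing C forces the intercept-only solution
        spec = ClassifierSpec("ridge", penalties=(1e-12,), internal_cv=3)
        rng = np.random.default_rng(0)
        y = np.array([0] * 30 + [1] * 10)
        x = rng.normal(size=(40, 15))
        probs = fit_predict_fold(x, y, x[:5], spec)
        assert np.allclose(probs, probs[0], atol=1e-4)
        assert probs[0] == pytest.approx(0.25, abs=0.02)  # training patient fraction
        assert np.all(labels_from_probs(probs) == 0)  # majority class

    def test_single_class_training_rejected(self, fast_ridge):
        x = np.zeros((10, 4))
        with pytest.raises(ConfigurationError):
            fit_predict_fold(x, np.zeros(10), x, fast_ridge)

    def test_tie_probability_predicts_control(self):
        assert labels_from_probs(np.array([0.5, 0.5001, 0.4999])).tolist() == [0, 1, 0]


class TestCrossValidateUnimodal:
    def test_every_subject_predicted_once(self, small_cohort, small_plan, fast_ridge):
        res = cross_validate_unimodal(small_cohort, "A", fast_ridge, small_plan)
        assert len(res.table) == small_cohort.n_subjects
        assert res.table["subject"].is_unique
        assert res.table["source"].eq("A").all()
        assert res.table["algorithm"].eq("ridge").all()

    def test_all_zero_features_majority(self, fast_ridge):
        cohort = generate_cohort(small_spec(effect_size_per_modality=0.0, noise_sd=1.0))
        for m in cohort.data:
            cohort.data[m][:] = 0.0
        cohort.age[:] = 40.0  # also constant confounds -> intercept only
        cohort.sex[:] = 1
        plan = make_folds(cohort.labels, 5, seed=0)
        with pytest.warns(UserWarning):
            res = cross_validate_unimodal(cohort, "A", fast_ridge, plan)
        # balanced groups: constant probability = training patient fraction ~ 0.5
        assert res.table["prob_patient"].std() < 0.02

    def test_deterministic_rerun(self, small_cohort, small_plan, fast_ridge):
        a = cross_validate_unimodal(small_cohort, "A", fast_ridge, small_plan)
        b = cross_validate_unimodal(small_cohort, "A", fast_ridge, small_plan)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_high_signal_accuracy(self, fast_ridge):
        # strong-signal modality comfortably beats 0.75
        for seed in (0, 1):
            cohort = generate_cohort(
                small_spec(
                    n_voxels=2000,
                    n_controls=105,
                    n_patients=106,
                    signal_count_per_modality=200,
                    effect_size_per_modality=1.2,
                    seed=seed,
                )
            )
            plan = make_folds(cohort.labels, 10, seed=seed)
            res = cross_validate_unimodal(cohort, "A", fast_ridge, plan)
            assert res.table["correct"].mean() > 0.75

    def test_leakage_canary_probs_independent_of_test_labels(
        self, small_cohort, small_plan, fast_ridge
    ):
        res = cross_validate_unimodal(small_cohort, "A", fast_ridge, small_plan)
        flipped = generate_cohort(small_spec())
        fold0 = small_plan.test_indices(0)
        flipped.labels = flipped.labels.copy()
        flipped.labels[fold0] = 1 - flipped.labels[fold0]
        res2 = cross_validate_unimodal(flipped, "A", fast_ridge, small_plan)
        a = res.table[res.table["fold"] == 0].sort_values("subject")
        b = res2.table[res2.table["fold"] == 0].sort_values("subject")
        np.testing.assert_allclose(
            a["prob_patient"].to_numpy(), b["prob_patient"].to_numpy(), atol=1e-12
        )
        assert not np.array_equal(a["correct"].to_numpy(), b["correct"].to_numpy())

    def test_missing_modality(self, small_cohort, small_plan, fast_ridge):
        with pytest.raises(ConfigurationError):
            cross_validate_unimodal(small_cohort, "missing", fast_ridge, small_plan)


class TestAccuracySummary:
    def _table(self, correct):
        n = len(correct)
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "fold": np.arange(n) % 5,
                "source": "A",
                "algorithm": "ridge",
                "prob_patient": 0.7,
                "predicted": 1,
                "correct": correct,
            }
        )

    def test_all_correct(self):
        s = accuracy_summary(self._table(np.ones(50, int)), n_boot=100, seed=0)
        assert s.mean == 1.0
        assert (s.ci_low, s.ci_high) == (1.0, 1.0)
        assert (s.fold_min, s.fold_max) == (1.0, 1.0)

    def test_arithmetic(self):
        correct = np.array([1] * 150 + [0] * 61)
        s = accuracy_summary(self._table(correct), n_boot=200, seed=0)
        assert s.mean == pytest.approx(150 / 211)

    def test_bootstrap_seeded(self):
        correct = (np.arange(100) % 3 > 0).astype(int)
        a = accuracy_summary(self._table(correct), n_boot=500, seed=9)
        b = accuracy_summary(self._table(correct), n_boot=500, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            accuracy_summary(self._table(np.array([], dtype=int)))
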