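from math import ceil

import numpy as np
import pytest

from neurofuse.cohort import generate_cohort
from neurofuse.crossval import ClassifierSpec, cross_validate_unimodal, make_folds
from neurofuse.errors import ConfigurationError, UndefinedStatisticError
from neurofuse.fusion_twostep import (
    SelectionMask,
    SelectionRule,
    mean_overlap,
    merge_and_refit,
    select_voxels,
    selection_overlap,
    twostep_cv,
)

from conftest import small_spec


class FakeLinearModel:
    def __init__(self, coef):
        self.coef_ = np.atleast_2d(coef)


class FakeTreeModel:
    def __init__(self, importances):
        self.feature_importances_ = np.asarray(importances)


class TestSelectionRule:
    def test_invalid_fraction(self):
        with pytest.raises(ConfigurationError):
            SelectionRule(family="ridge", mode="top_fraction", fraction=0.0)

    def test_defaults_per_family(self):
        assert SelectionRule.default_for("ridge").mode == "top_fraction"
        assert SelectionRule.default_for("ridge").fraction == 0.2
        assert SelectionRule.default_for("lasso").mode == "nonzero"
        assert SelectionRule.default_for("random_forest").fraction == 0.2
        assert SelectionRule.default_for("gradient_boosting").mode == "nonzero"


class TestSelectVoxels:
    def test_top_fraction_exact_count(self, rng):
        model = FakeLinearModel(rng.normal(size=2000))
        mask = select_voxels(model, SelectionRule("ridge", "top_fraction", 0.2))
        assert mask.size == ceil(0.2 * 2000) == 400

    def test_magnitude_not_sign(self):
        model = FakeLinearModel([-5.0, 0.1, 4.0, -0.2])
        mask = select_voxels(model, SelectionRule("ridge", "top_fraction", 0.5))
        assert mask.indices.tolist() == [0, 2]

    def test_tie_break_lower_index(self):
        model = FakeLinearModel([1.0, 2.0, 2.0, 2.0])
        mask = select_voxels(model, SelectionRule("ridge", "top_fraction", 0.5))
        assert mask.indices.tolist() == [1, 2]

    def test_nonzero_count(self, rng):
        coef = np.zeros(500)
        idx = rng.choice(500, 37, replace=False)
        coef[idx] = rng.normal(size=37)
        mask = select_voxels(FakeLinearModel(coef), SelectionRule("lasso", "nonzero"))
        assert mask.size == 37
        np.testing.assert_array_equal(mask.indices, np.sort(idx))

    def test_all_zero_nonzero_mode_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = select_voxels(
                FakeTreeModel(np.zeros(10)), SelectionRule("gradient_boosting", "nonzero")
            )
        assert mask.size == 0

    def test_signal_recovery(self):
        # top-20% ridge selection recovers most true signal voxels
        recoveries = []
        for seed in range(3):
            cohort = generate_cohort(
                small_spec(
                    n_voxels=1000,
                    n_controls=105,
                    n_patients=106,
                    signal_count_per_modality=100,
                    effect_size_per_modality=1.5,
                    seed=seed,
                )
            )
            plan = make_folds(cohort.labels, 5, seed=seed)
            spec = ClassifierSpec("ridge", n_penalties=4, internal_cv=3)
            res = cross_validate_unimodal(cohort, "A", spec, plan)
            mask = select_voxels(res.folds[0].model, SelectionRule.default_for("ridge"))
            truth = cohort.truth_masks["A"]
            recoveries.append(len(np.intersect1d(mask.indices, truth)) / len(truth))
        assert np.mean(recoveries) >= 0.8


class TestSelectionOverlap:
    def test_identical_masks(self):
        idx = np.arange(200)
        joint, contain = selection_overlap(idx, idx, 1000)
        assert contain == 1.0
        assert joint == pytest.approx(0.2)

    def test_set_arithmetic_example(self):
        a = np.arange(200)
        b = np.arange(121, 321)  # overlap = 79
        joint, contain = selection_overlap(a, b, 1000)
        assert joint == pytest.approx(0.079)
        assert contain == pytest.approx(0.395)

    def test_empty_mask_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            selection_overlap(np.array([], dtype=int), np.arange(5), 100)

    def test_independent_joint_fraction_expectation(self, rng):
        # E[joint] = q_a * q_b under independent uniform selection
        v, qa, qb, draws = 10_000, 0.2, 0.2, 300
        vals = []
        for _ in range(draws):
            a = rng.choice(v, int(qa * v), replace=False)
            b = rng.choice(v, int(qb * v), replace=False)
            vals.append(selection_overlap(a, b, v)[0])
        assert abs(np.mean(vals) - qa * qb) < 0.005


@pytest.fixture(scope="module")
def disjoint_setup():
    cohort = generate_cohort(
        small_spec(
            n_voxels=600,
            n_controls=80,
            n_patients=80,
            signal_count_per_modality=60,
            effect_size_per_modality=1.0,
            seed=17,
        )
    )
    plan = make_folds(cohort.labels, 5, seed=3)
    spec = ClassifierSpec("ridge", n_penalties=4, internal_cv=3)
    unimodal = {m: cross_validate_unimodal(cohort, m, spec, plan) for m in cohort.modalities}
    return cohort, plan, spec, unimodal


class TestMergeAndRefit:
    def test_single_modality_full_fraction_reduces_to_unimodal(self, disjoint_setup):
        cohort, plan, spec, unimodal = disjoint_setup
        rule = SelectionRule("ridge", "top_fraction", 1.0)
        masks = {"A": select_voxels(unimodal["A"].folds[0].model, rule, "A", 0)}
        assert masks["A"].size == cohort.n_voxels
        probs, _ = merge_and_refit(cohort, masks, spec, plan, 0)
        np.testing.assert_allclose(probs, unimodal["A"].folds[0].test_probs, atol=1e-8)

    def test_all_empty_masks_rejected(self, disjoint_setup):
        cohort, plan, spec, _ = disjoint_setup
        empty = SelectionMask("A", 0, np.array([], dtype=int), np.array([]))
        with pytest.raises(ConfigurationError):
            merge_and_refit(cohort, {"A": empty}, spec, plan, 0)

    def test_one_empty_mask_contributes_nothing(self, disjoint_setup):
        cohort, plan, spec, unimodal = disjoint_setup
        rule = SelectionRule("ridge", "top_fraction", 0.2)
        masks = {
            "A": select_voxels(unimodal["A"].folds[0].model, rule, "A", 0),
            "B": SelectionMask("B", 0, np.array([], dtype=int), np.array([])),
        }
        with pytest.warns(UserWarning, match="no columns"):
            probs, _ = merge_and_refit(cohort, masks, spec, plan, 0)
        only_a, _ = merge_and_refit(cohort, {"A": masks["A"]}, spec, plan, 0)
        np.testing.assert_allclose(probs, only_a, atol=1e-10)

    def test_duplicated_modality_within_noise_of_single(self, disjoint_setup):
        cohort, plan, spec, unimodal = disjoint_setup
        rule = SelectionRule("ridge", "top_fraction", 0.2)
        mask_a = select_voxels(unimodal["A"].folds[0].model, rule, "A", 0)
        single, _ = merge_and_refit(cohort, {"A": mask_a}, spec, plan, 0)
        cohort.data["A2"] = cohort.data["A"]
        try:
            mask_a2 = SelectionMask("A2", 0, mask_a.indices, mask_a.scores)
            doubled, _ = merge_and_refit(
                cohort, {"A": mask_a, "A2": mask_a2}, spec, plan, 0
            )
        finally:
            del cohort.data["A2"]
        lab_single = single > 0.5
        lab_doubled = doubled > 0.5
        assert np.mean(lab_single == lab_doubled) > 0.85


class TestTwostepCV:
    def test_full_run_outputs(self, disjoint_setup):
        cohort, plan, spec, unimodal = disjoint_setup
        table, fold_masks, overlaps = twostep_cv(cohort, unimodal, spec, plan)
        assert len(table) == cohort.n_subjects
        assert table["source"].eq("twostep").all()
        assert len(fold_masks) == plan.n_folds
        # ridge: exactly ceil(0.2 * V) voxels per modality per fold
        for masks in fold_masks:
            for m in cohort.modalities:
                assert masks[m].size == ceil(0.2 * cohort.n_voxels)
        assert set(overlaps.columns) >= {"joint_fraction", "containment"}
        avg = mean_overlap(overlaps)
        assert len(avg) == 1  # one unordered pair for two modalities

    def test_selection_ignores_test_rows(self, disjoint_setup):
        # leakage canary: perturbing a fold-0 test subject's maps must not
        # change fold-0 selection masks
        cohort, plan, spec, unimodal = disjoint_setup
        _, fold_masks, _ = twostep_cv(cohort, unimodal, spec, plan)
        perturbed = generate_cohort(cohort.spec)
        victim = plan.test_indices(0)[0]
        perturbed.data["A"][victim] += 50.0
        uni2 = {
            m: cross_validate_unimodal(perturbed, m, spec, plan)
            for m in perturbed.modalities
        }
        _, fold_masks2, _ = twostep_cv(perturbed, uni2, spec, plan)
        for m in cohort.modalities:
            np.testing.assert_array_equal(
                fold_masks[0][m].indices, fold_masks2[0][m].indices
            )
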