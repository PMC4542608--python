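"""Resampled-evaluation tests: split integrity, chance levels, ROC and
diagnostic-metric oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from otoraman import (
    ResamplingPlan,
    balanced_resample_evaluate,
    binary_metrics,
    binary_task,
    negative_control,
    roc_curve,
)
from otoraman.screen import assigned_labels, screen_dataset

MINERAL = "mineralized_myringosclerosis"


@pytest.fixture(scope="module")
def small_labels(small_dataset):
    return assigned_labels(screen_dataset(small_dataset), small_dataset)


class TestBalancedResample:
    def test_identical_plans_give_identical_reports(self, small_dataset, small_labels):
        plan = ResamplingPlan(n_iterations=1, rng_seed=42)
        a = balanced_resample_evaluate(small_dataset, small_labels, plan, n_components=2)
        b = balanced_resample_evaluate(small_dataset, small_labels, plan, n_components=2)
        np.testing.assert_array_equal(a.confusions, b.confusions)

    def test_train_and_test_sites_disjoint_every_iteration(
        self, small_dataset, small_labels
    ):
        plan = ResamplingPlan(n_iterations=25, rng_seed=9)
        report = balanced_resample_evaluate(
            small_dataset, small_labels, plan, n_components=2
        )
        assert len(report.site_splits) == 25
        for train, test in report.site_splits:
            assert not train & test
            assert train and test

    def test_balancing_equalizes_test_row_sums(self, small_dataset, small_labels):
        plan = ResamplingPlan(n_iterations=5, rng_seed=3)
        report = balanced_resample_evaluate(
            small_dataset, small_labels, plan, n_components=2
        )
        # per iteration each class contributes the same number of test sites
        for cm in report.confusions:
            assert len(set(cm.sum(axis=1))) == 1

    def test_class_with_single_site_rejected(self, small_dataset):
        labels = np.array(
            ["solo"] + ["rest"] * (small_dataset.n_spectra - 1)
        )
        with pytest.raises(ValueError, match="fewer than 2 sites"):
            balanced_resample_evaluate(small_dataset, labels, ResamplingPlan(rng_seed=0))


class TestNegativeControl:
    def test_three_class_control_collapses_to_chance(self, small_dataset, small_labels):
        plan = ResamplingPlan(n_iterations=100, rng_seed=17)
        report = negative_control(small_dataset, small_labels, plan, n_components=3)
        assert report.overall_rate == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_two_class_control_collapses_to_chance(self, small_dataset, small_labels):
        ds, labels = binary_task(small_dataset, small_labels, MINERAL, "cholesteatoma")
        plan = ResamplingPlan(n_iterations=100, rng_seed=23)
        report = negative_control(ds, labels, plan, n_components=3)
        assert report.overall_rate == pytest.approx(0.5, abs=0.05)

    def test_identity_permutation_reproduces_true_evaluation(
        self, small_dataset, small_labels
    ):
        plan = ResamplingPlan(n_iterations=5, rng_seed=31)
        truth = balanced_resample_evaluate(
            small_dataset, small_labels, plan, n_components=2
        )
        debug = negative_control(
            small_dataset, small_labels, plan, n_components=2, _permutation="identity"
        )
        np.testing.assert_array_equal(truth.confusions, debug.confusions)


class TestRocCurve:
    def test_hand_example_matches_pair_count_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        truth = np.array([0, 0, 1, 1], dtype=bool)
        points, auc = roc_curve(scores, truth)
        # Mann-Whitney pair counting: (pos, neg) score pairs won / total
        wins = sum(
            (s > t) + 0.5 * (s == t)
            for s in scores[truth]
            for t in scores[~truth]
        )
        assert auc == wins / (truth.sum() * (~truth).sum()) == 0.75
        np.testing.assert_allclose(points[0], [0.0, 0.0])
        np.testing.assert_allclose(points[-1], [1.0, 1.0])

    def test_perfect_separation_gives_unit_auc(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        _, auc = roc_curve(scores, np.array([0, 0, 1, 1], dtype=bool))
        assert auc == 1.0

    def test_uninformative_scores_give_half_auc(self, rng):
        scores = rng.uniform(size=4000)
        truth = rng.uniform(size=4000) < 0.5
        _, auc = roc_curve(scores, truth)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn_auc_with_ties(self, rng):
        scores = rng.integers(0, 10, size=200).astype(float)  # heavy ties
        truth = rng.uniform(size=200) < 0.4
        _, auc = roc_curve(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_curve_is_monotone(self, rng):
        scores = rng.standard_normal(100)
        truth = rng.uniform(size=100) < 0.5
        points, _ = roc_curve(scores, truth)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1], dtype=bool))


class TestBinaryMetrics:
    def test_balanced_example(self):
        m = binary_metrics(tp=9, fp=1, fn=1, tn=9)
        assert (m.ppv, m.npv, m.sensitivity, m.specificity, m.accuracy) == (
            0.9,
            0.9,
            0.9,
            0.9,
            0.9,
        )

    def test_error_free_confusion_gives_all_ones(self):
        m = binary_metrics(tp=7, fp=0, fn=0, tn=13)
        assert (m.ppv, m.npv, m.sensitivity, m.specificity, m.accuracy) == (
            1.0,
        ) * 5

    def test_asymmetric_example_against_direct_arithmetic(self):
        m = binary_metrics(tp=95, fp=1, fn=5, tn=99)
        assert m.ppv == pytest.approx(95 / 96)
        assert m.npv == pytest.approx(99 / 104)
        assert m.sensitivity == pytest.approx(0.95)
        assert m.specificity == pytest.approx(99 / 100)
        assert m.accuracy == pytest.approx(194 / 200)

    def test_zero_denominator_flagged_undefined_not_zero(self):
        m = binary_metrics(tp=0, fp=0, fn=3, tn=7)
        assert np.isnan(m.ppv)
        assert "ppv" in m.undefined
        assert m.npv == 0.7

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(tp=-1, fp=0, fn=0, tn=0)
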