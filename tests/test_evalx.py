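import itertools

import numpy as np
import pytest

from hiegrade.evalx import (
    GRADES,
    FoldPlan,
    PlanningError,
    classification_metrics,
    clustering_metrics,
    compare_paired,
    convnext_nano_layers,
    distance_auc,
    make_nested_folds,
    overall_accuracy,
    receptive_field,
    regression_metrics,
    run_nested_cv,
    tolerance_accuracy,
)
from hiegrade.grading import oracle_predictor_factory


def _patient_dataset(n_patients=20, records_per_patient=4, seed=0):
    rng = np.random.default_rng(seed)
    grades = np.repeat(np.tile([1, 2, 3, 4], n_patients // 4), records_per_patient)
    groups = np.repeat([f"p{i}" for i in range(n_patients)], records_per_patient)
    return grades, groups


class TestMakeNestedFolds:
    def test_outer_folds_disjoint_and_exhaustive(self):
        grades, groups = _patient_dataset()
        plan = make_nested_folds(grades, groups, seed=1)
        assert plan.k_outer == 5
        pooled = np.concatenate(plan.outer_test)
        assert sorted(pooled) == list(range(grades.size))

    def test_no_patient_straddles_any_split(self):
        grades, groups = _patient_dataset()
        plan = make_nested_folds(grades, groups, seed=2)
        n = grades.size
        for k, test_idx in enumerate(plan.outer_test):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            # brute-force membership scan
            for p in set(groups[test_idx]):
                assert p not in set(groups[train_idx])
            for tr, va in plan.inner[k]:
                for p in set(groups[va]):
                    assert p not in set(groups[tr])

    def test_folds_roughly_stratified(self):
        grades, groups = _patient_dataset()
        plan = make_nested_folds(grades, groups, seed=3)
        for test_idx in plan.outer_test:
            present = set(grades[test_idx])
            assert present == {1, 2, 3, 4}

    def test_single_grade_rejected(self):
        grades = np.ones(40, dtype=int)
        groups = np.repeat([f"p{i}" for i in range(10)], 4)
        with pytest.raises(PlanningError):
            make_nested_folds(grades, groups)

    def test_too_few_patients_rejected(self):
        grades = np.array([1, 2, 3, 4])
        groups = np.array(["a", "a", "b", "b"])
        with pytest.raises(PlanningError):
            make_nested_folds(grades, groups, k_outer=5)

    def test_validate_catches_tampered_plan(self):
        grades, groups = _patient_dataset()
        plan = make_nested_folds(grades, groups, seed=4)
        plan.outer_test[0] = plan.outer_test[0][:-1]  # drop a sample
        with pytest.raises(PlanningError):
            plan.validate()


class TestOverallAccuracy:
    def test_all_correct_and_all_wrong(self):
        truths = np.array([1, 2, 3, 4])
        idx = [np.array([0, 1]), np.array([2, 3])]
        assert overall_accuracy(idx, [truths[:2], truths[2:]], truths) == 1.0
        wrong = [np.array([4, 4]), np.array([1, 1])]
        assert overall_accuracy(idx, wrong, truths) == 0.0

    def test_matches_pooled_counting_oracle(self, rng):
        truths = rng.integers(1, 5, 50)
        perm = rng.permutation(50)
        folds = np.array_split(perm, 5)
        preds = [rng.integers(1, 5, f.size) for f in folds]
        acc = overall_accuracy(folds, preds, truths)
        total = sum(
            int(p == truths[i])
            for f, pr in zip(folds, preds)
            for i, p in zip(f, pr)
        )
        assert acc == pytest.approx(total / 50)

    def test_coverage_gap_rejected(self):
        truths = np.array([1, 2, 3, 4])
        with pytest.raises(ValueError):
            overall_accuracy([np.array([0, 1])], [np.array([1, 2])], truths)

    def test_equals_size_weighted_mean_of_fold_accuracies(self, rng):
        truths = rng.integers(1, 5, 37)
        perm = rng.permutation(37)
        folds = [perm[:10], perm[10:14], perm[14:37]]
        preds = [rng.integers(1, 5, f.size) for f in folds]
        acc = overall_accuracy(folds, preds, truths)
        weighted = sum(
            f.size * np.mean(p == truths[f]) for f, p in zip(folds, preds)
        ) / 37
        assert acc == pytest.approx(weighted)


class TestDistanceAuc:
    def test_perfect_predictions_give_unit_auc(self):
        truths = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        for g in GRADES:
            assert distance_auc(truths.astype(float), truths, g) == 1.0

    def test_constant_predictions_give_half(self):
        truths = np.array([1, 2, 3, 4, 1, 2])
        assert distance_auc(np.full(6, 2.0), truths, 1) == pytest.approx(0.5)

    def test_matches_mann_whitney_pairwise_oracle(self, rng):
        truths = rng.integers(1, 5, 12)
        while np.unique(truths).size < 2:
            truths = rng.integers(1, 5, 12)
        preds = truths + rng.normal(0, 1.0, 12)
        target = int(truths[0])
        score = 1.0 - np.abs(preds - target)
        pos = score[truths == target]
        neg = score[truths != target]
        u = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        )
        oracle = u / (pos.size * neg.size)
        assert distance_auc(preds, truths, target) == pytest.approx(oracle)

    def test_invariant_under_monotone_transform_of_distance(self, rng):
        # AUC depends only on the ranking of |pred - class|
        truths = rng.integers(1, 5, 30)
        preds = truths + rng.normal(0, 0.7, 30)
        a = distance_auc(preds, truths, 2)
        shrunk = 2 + (preds - 2) * 0.25  # monotone shrink toward the class
        b = distance_auc(shrunk, truths, 2)
        assert a == pytest.approx(b)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            distance_auc(np.array([1.0, 2.0]), np.array([1, 2]), 4)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        truths = np.array([1, 2, 3, 4, 2, 3])
        m = classification_metrics(truths, truths)
        assert m["precision"] == m["recall"] == m["f1"] == 1.0
        assert m["cohen_kappa"] == 1.0
        assert np.all(np.diag(m["confusion_matrix"]) > 0)
        assert m["confusion_matrix"].sum() == np.trace(m["confusion_matrix"])

    def test_constant_predictions_have_zero_kappa(self):
        truths = np.array([1, 2, 3, 4] * 5)
        m = classification_metrics(np.full(20, 2), truths)
        assert m["cohen_kappa"] == pytest.approx(0.0)

    def test_matches_hand_derived_toy_confusion(self):
        # truths: three 1s, two 2s, one 3, two 4s
        truths = np.array([1, 1, 1, 2, 2, 3, 4, 4])
        preds = np.array([1, 1, 2, 2, 2, 3, 4, 3])
        m = classification_metrics(preds, truths)
        cm = m["confusion_matrix"]
        assert cm[0, 0] == 2 and cm[0, 1] == 1  # one grade-1 called 2
        assert cm[3, 2] == 1  # one grade-4 called 3
        assert cm.sum(axis=1).tolist() == [3, 2, 1, 2]  # row sums = support
        # weighted recall: (3*(2/3) + 2*1 + 1*1 + 2*(1/2)) / 8
        assert m["recall"] == pytest.approx((2 + 2 + 1 + 1) / 8)
        # weighted precision: preds per class 1:2,2:3,3:2,4:1
        per_class_prec = [2 / 2, 2 / 3, 1 / 2, 1 / 1]
        support = [3, 2, 1, 2]
        expected = sum(p * s for p, s in zip(per_class_prec, support)) / 8
        assert m["precision"] == pytest.approx(expected)

    def test_weighted_recall_equals_accuracy(self, rng):
        truths = rng.integers(1, 5, 60)
        preds = rng.integers(1, 5, 60)
        m = classification_metrics(preds, truths)
        assert m["recall"] == pytest.approx(m["accuracy"])


class TestRegressionMetrics:
    def test_exact_predictions(self):
        truths = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(truths, truths)
        assert m["mse"] == 0.0 and m["r_squared"] == 1.0

    def test_mean_predictor_has_zero_r_squared(self):
        truths = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(np.full(4, truths.mean()), truths)
        assert m["r_squared"] == pytest.approx(0.0)

    def test_matches_formula_oracle(self, rng):
        truths = rng.integers(1, 5, 25).astype(float)
        preds = truths + rng.normal(0, 0.5, 25)
        m = regression_metrics(preds, truths)
        mse = np.mean((preds - truths) ** 2)
        ss_res = np.sum((truths - preds) ** 2)
        ss_tot = np.sum((truths - truths.mean()) ** 2)
        assert m["mse"] == pytest.approx(mse)
        assert m["r_squared"] == pytest.approx(1 - ss_res / ss_tot)

    def test_zero_variance_truths_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics(np.array([1.0, 2.0]), np.array([2.0, 2.0]))


class TestComparePaired:
    def test_identical_vectors_degenerate(self):
        with pytest.raises(ValueError):
            compare_paired(np.ones(5), np.ones(5))

    def test_symmetric_differences_give_p_one(self):
        a = np.array([0.5, 0.6, 0.7, 0.8])
        b = np.array([0.6, 0.5, 0.8, 0.7])  # mirrored +-0.1 differences
        assert compare_paired(a, b) == pytest.approx(1.0)

    def test_uniform_dominance_exact_p(self):
        # all five differences positive and distinct: the most extreme
        # rank-sum of 2^5 = 32 equally likely sign patterns, two-sided
        a = np.array([0.9, 0.8, 0.85, 0.95, 0.9])
        b = a - np.array([0.05, 0.04, 0.03, 0.02, 0.01])
        assert compare_paired(a, b) == pytest.approx(2 / 32)


class TestClusteringMetrics:
    def test_tight_far_clusters(self, rng):
        a = rng.normal(0, 0.01, size=(20, 2))
        b = rng.normal(0, 0.01, size=(20, 2)) + 10.0
        emb = np.vstack([a, b])
        labels = np.array([0] * 20 + [1] * 20)
        m = clustering_metrics(emb, labels)
        assert m["silhouette"] > 0.9
        assert m["dbi"] < 0.1
        assert m["chi"] > 1000

    def test_silhouette_matches_hand_computed_six_points(self):
        # two clusters on a line: {0, 1} and {10, 11, 12}, plus one point
        # at 2 in cluster A -> hand-derivable silhouette
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        m = clustering_metrics(x, labels)

        def sil(i):
            same = [j for j in range(6) if labels[j] == labels[i] and j != i]
            other = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean([abs(x[i, 0] - x[j, 0]) for j in same])
            b = np.mean([abs(x[i, 0] - x[j, 0]) for j in other])
            return (b - a) / max(a, b)

        expected = np.mean([sil(i) for i in range(6)])
        assert m["silhouette"] == pytest.approx(expected)

    def test_shuffled_labels_degrade_silhouette(self, rng):
        a = rng.normal(0, 0.5, size=(15, 3))
        b = rng.normal(0, 0.5, size=(15, 3)) + 4.0
        emb = np.vstack([a, b])
        labels = np.array([0] * 15 + [1] * 15)
        true_m = clustering_metrics(emb, labels)
        shuffled = rng.permutation(labels)
        shuf_m = clustering_metrics(emb, shuffled)
        assert shuf_m["silhouette"] < true_m["silhouette"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            clustering_metrics(np.zeros((5, 2)), np.zeros(5))


class TestRunNestedCv:
    def test_oracle_predictor_is_perfect_end_to_end(self):
        grades, groups = _patient_dataset()
        plan = make_nested_folds(grades, groups, seed=5)
        report = run_nested_cv(
            grades, plan, oracle_predictor_factory(grades), seed=5
        )
        assert report.overall_accuracy == 1.0
        assert all(a == 1.0 for a in report.distance_auc.values())
        assert report.mse == 0.0 and report.r_squared == 1.0

    def test_noisy_predictor_report_is_consistent(self):
        grades, groups = _patient_dataset()
        plan = make_nested_folds(grades, groups, seed=6)
        rng = np.random.default_rng(0)
        noisy = grades + rng.normal(0, 0.4, grades.size)

        def factory(train_idx, seed):
            return lambda idx: noisy[idx]

        report = run_nested_cv(grades, plan, factory, seed=6)
        # confusion-matrix row sums equal per-grade test counts
        counts = [int(np.sum(grades == g)) for g in GRADES]
        assert report.confusion_matrix.sum(axis=1).tolist() == counts
        assert len(report.per_fold_accuracy) == 5
        assert report.tolerance_accuracy >= report.overall_accuracy
        assert "overall accuracy" in report.summary()

    def test_tolerance_accuracy_dominates_exact(self, rng):
        rounded = rng.integers(1, 5, 40)
        truths = rng.integers(1, 5, 40)
        exact = float(np.mean(rounded == truths))
        assert tolerance_accuracy(rounded, truths) >= exact


class TestReceptiveField:
    def test_single_conv(self):
        assert receptive_field([(3, 1)]) == 3

    def test_two_stacked_convs_match_gradient_footprint_oracle(self):
        # footprint oracle: cascade of convolutions of indicator kernels
        x = np.zeros(31)
        x[15] = 1.0
        for _ in range(2):
            x = np.convolve(x, np.ones(3), mode="same")
        assert receptive_field([(3, 1), (3, 1)]) == int(np.sum(x > 0))

    def test_stride_compounds_jump(self):
        assert receptive_field([(4, 4), (3, 1)]) == 4 + 2 * 4

    def test_convnext_nano_value(self):
        assert receptive_field(convnext_nano_layers()) == 1328

    def test_invalid_layers_rejected(self):
        with pytest.raises(ValueError):
            receptive_field([(0, 1)])
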