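"""Nested CV mechanics: folding, tuning, metrics, leakage, consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fcclassify as fc

COMPACT = fc.SVMConfig.compact()


class TestFolds:
    def test_stratified_fold_sizes(self):
        y = np.repeat([0, 1], 20)
        plan = fc.make_folds(y, n_folds=10, seed=0)
        for f in range(10):
            te = plan.test_indices(f)
            assert te.size == 4
            assert np.sum(y[te] == 0) == 2 and np.sum(y[te] == 1) == 2

    def test_partition_property(self):
        y = np.repeat([0, 1], [17, 23])
        plan = fc.make_folds(y, n_folds=5, seed=3)
        seen = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(seen) == list(range(40))

    def test_seed_determinism(self):
        y = np.repeat([0, 1], 20)
        a = fc.make_folds(y, seed=1).assignment
        b = fc.make_folds(y, seed=1).assignment
        c = fc.make_folds(y, seed=2).assignment
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_degenerate_inputs_rejected(self):
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError):
            fc.make_folds(y, n_folds=1)
        with pytest.raises(ValueError, match="stratified"):
            fc.make_folds(np.repeat([0, 1], [4, 36]), n_folds=10)


class TestTuneSVM:
    def test_separable_blobs_high_inner_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-3, 0.5, size=(30, 2)),
                       rng.normal(3, 0.5, size=(30, 2))])
        y = np.repeat([0, 1], 30)
        c, scale, acc = fc.tune_svm(x, y, COMPACT, seed=0)
        assert acc >= 0.95

    def test_grid_of_one_returned_verbatim(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        cfg = fc.SVMConfig(c_grid=(2.0,), scale_factors=(1.0,), inner_folds=2)
        c, scale, _ = fc.tune_svm(x, y, cfg, seed=0)
        assert c == 2.0
        assert scale == pytest.approx(np.sqrt(3))

    def test_shuffled_labels_near_chance(self):
        # the best-of-grid inner accuracy is selection-biased upward, so the
        # bound is generous but still far below a real signal
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 4))
        y = rng.permutation(np.repeat([0, 1], 30))
        _, _, acc = fc.tune_svm(x, y, COMPACT, seed=0)
        assert 0.3 <= acc <= 0.78

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fc.tune_svm(np.zeros((10, 2)), np.zeros(10), COMPACT)


class TestMetrics:
    def test_perfect_prediction(self):
        m = fc.classification_metrics([1, 1, 0, 0], [1, 1, 0, 0],
                                      [3.0, 2.0, -1.0, -2.0])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0
        assert m["auc"] == 1.0

    def test_constant_scores_give_half_auc(self):
        m = fc.classification_metrics([1, 0, 1, 0], [1, 1, 1, 1],
                                      [0.7, 0.7, 0.7, 0.7])
        assert m["auc"] == pytest.approx(0.5)

    def test_pairwise_concordance_example(self):
        # 4 patient-control pairs, 3 concordant -> AUC 0.75
        m = fc.classification_metrics([1, 1, 0, 0], [1, 0, 1, 0],
                                      [0.9, 0.4, 0.6, 0.1])
        assert m["auc"] == pytest.approx(0.75)

    def test_accuracy_equals_confusion_count(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        pred = rng.integers(0, 2, size=200)
        m = fc.classification_metrics(y, pred)
        assert m["accuracy"] == np.mean(y == pred)

    def test_single_class_truth_flags_auc(self):
        m = fc.classification_metrics([1, 1], [1, 0], [0.2, 0.1])
        assert not m["auc_defined"] and np.isnan(m["auc"])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_auc_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        s = rng.normal(size=8)
        base = fc.classification_metrics(y, y, s)["auc"]
        for g in (lambda v: 3 * v + 2, np.tanh, lambda v: np.exp(v / 2)):
            assert fc.classification_metrics(y, y, g(s))["auc"] == \
                pytest.approx(base, abs=1e-12)


class TestNestedCV:
    def test_each_subject_predicted_once(self, small_cohort):
        x, y, _ = small_cohort
        cv = fc.run_nested_cv(x, y, seed=1, svm_config=COMPACT, n_outer=4,
                              max_k=15)
        assert cv.predictions.size == y.size
        assert np.all(cv.predictions >= 0)
        assert np.all(np.isfinite(cv.scores))

    def test_strong_signal_high_accuracy(self, small_cohort):
        x, y, _ = small_cohort
        cv = fc.run_nested_cv(x, y, seed=2, svm_config=COMPACT, n_outer=4,
                              max_k=15)
        assert cv.mean_accuracy >= 0.8

    def test_no_leakage_from_test_folds(self, small_cohort):
        """Per-fold selection, tuning and scaling must be invariant to
        arbitrary corruption of that fold's test subjects."""
        x, y, _ = small_cohort
        cv1 = fc.run_nested_cv(x, y, seed=5, svm_config=COMPACT, n_outer=4,
                               max_k=15)
        rng = np.random.default_rng(99)
        for fold in (0, 2):
            x2 = x.copy()
            te = cv1.folds[fold].test_indices
            x2[te] = rng.normal(50, 100, size=(te.size, x.shape[1]))
            cv2 = fc.run_nested_cv(x2, y, seed=5, svm_config=COMPACT,
                                   n_outer=4, max_k=15)
            np.testing.assert_array_equal(cv2.folds[fold].selected,
                                          cv1.folds[fold].selected)
            assert cv2.folds[fold].c == cv1.folds[fold].c
            assert cv2.folds[fold].scale == cv1.folds[fold].scale

    def test_fold_summary_recomputable_from_fold_metrics(self, small_cohort):
        x, y, _ = small_cohort
        cv = fc.run_nested_cv(x, y, seed=3, svm_config=COMPACT, n_outer=4,
                              max_k=15)
        accs = [f.metrics["accuracy"] for f in cv.folds]
        assert cv.summary["accuracy_mean"] == pytest.approx(np.mean(accs))
        assert cv.summary["accuracy_sd"] == pytest.approx(np.std(accs, ddof=1))


class TestRepetitions:
    def test_single_repetition_is_optimal(self, small_cohort):
        x, y, _ = small_cohort
        rep = fc.repeat_partitions(x, y, n_repetitions=1, base_seed=4,
                                   svm_config=COMPACT, n_outer=4, max_k=15)
        assert rep.optimal_index == 0
        assert len(rep.summary) == 1

    def test_same_base_seed_reproduces(self, small_cohort):
        x, y, _ = small_cohort
        a = fc.repeat_partitions(x, y, n_repetitions=2, base_seed=8,
                                 svm_config=COMPACT, n_outer=4, max_k=15)
        b = fc.repeat_partitions(x, y, n_repetitions=2, base_seed=8,
                                 svm_config=COMPACT, n_outer=4, max_k=15)
        assert a.summary.equals(b.summary)
        assert a.optimal_index == b.optimal_index

    def test_aggregate_reports_mean_and_sd(self, small_cohort):
        x, y, _ = small_cohort
        rep = fc.repeat_partitions(x, y, n_repetitions=3, base_seed=0,
                                   svm_config=COMPACT, n_outer=4, max_k=15)
        agg = rep.aggregate()
        for m in ("accuracy", "sensitivity", "specificity", "auc"):
            assert 0.0 <= agg[f"{m}_mean"] <= 1.0
            assert agg[f"{m}_sd"] >= 0.0


class TestMajorFeatures:
    def test_planted_edges_dominate_consensus(self, strong_cohort):
        # the elbow rule keeps only a handful of edges per fold at this
        # scale, so consensus is read at a fold majority rather than 9/10
        x, y, truth = strong_cohort
        cv = fc.run_nested_cv(x, y, seed=6, svm_config=COMPACT, max_k=30)
        mf = fc.major_features(cv, x, y, min_count=6)
        assert len(mf) > 0
        planted = set(truth.planted_indices)
        frac = np.mean([e in planted for e in mf["edge"]])
        assert frac >= 0.7

    def test_min_count_above_folds_gives_empty_report(self, small_cohort):
        x, y, _ = small_cohort
        cv = fc.run_nested_cv(x, y, seed=1, svm_config=COMPACT, n_outer=4,
                              max_k=15)
        assert len(fc.major_features(cv, x, y, min_count=5)) == 0

    def test_sign_annotation_matches_group_means(self, strong_cohort):
        x, y, truth = strong_cohort
        cv = fc.run_nested_cv(x, y, seed=6, svm_config=COMPACT, max_k=30)
        mf = fc.major_features(cv, x, y, min_count=6)
        assert len(mf) > 0
        for _, row in mf.iterrows():
            diff = x[y == 1, row["edge"]].mean() - x[y == 0, row["edge"]].mean()
            assert row["patients_higher"] == (diff > 0)


class TestControls:
    def test_random_subset_reproducible(self, small_cohort):
        x, y, _ = small_cohort
        a = fc.control_experiment(x, y, "random", 10, seed=3,
                                  svm_config=COMPACT, n_outer=4)
        b = fc.control_experiment(x, y, "random", 10, seed=3,
                                  svm_config=COMPACT, n_outer=4)
        np.testing.assert_array_equal(a.folds[0].selected, b.folds[0].selected)
        assert a.mean_accuracy == b.mean_accuracy

    def test_full_feature_set_identical_across_modes(self, small_cohort):
        x, y, _ = small_cohort
        e = x.shape[1]
        low = fc.control_experiment(x, y, "low_score", e, seed=3,
                                    svm_config=COMPACT, n_outer=4)
        rand = fc.control_experiment(x, y, "random", e, seed=3,
                                     svm_config=COMPACT, n_outer=4)
        assert sorted(low.folds[0].selected) == list(range(e))
        assert sorted(rand.folds[0].selected) == list(range(e))
        assert low.mean_accuracy == rand.mean_accuracy

    def test_unknown_mode_rejected(self, small_cohort):
        x, y, _ = small_cohort
        with pytest.raises(ValueError, match="mode"):
            fc.control_experiment(x, y, "best", 5)
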