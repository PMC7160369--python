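import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vfforage.errors import UndefinedMetricError, ValidationError
from vfforage.ml import (ClassifierConfig, FeatureMatrix,
                         RobustQuantileScaler, auc_roc, impute_median,
                         iter_lopo_folds, lopo_cv, rfecv_select, robust_scale,
                         sensitivity_specificity)


def brute_force_auc(scores, labels):
    """Oracle: concordant-pair fraction with ties counted one half."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = concordant = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


def make_matrix(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    data = pd.DataFrame(X, columns=names,
                        index=[f"s{i}" for i in range(len(X))])
    labels = pd.Series(np.where(np.asarray(y) == 1, "MCI", "CI"),
                       index=data.index)
    return FeatureMatrix(data=data, labels=labels)


class TestRobustQuantileScaler:
    def test_five_point_column(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        out = RobustQuantileScaler("q1").fit_transform(X)
        np.testing.assert_allclose(out.ravel(), [-0.5, 0, 0.5, 1.0, 1.5])

    def test_q1_maps_to_zero_q3_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        scaler = RobustQuantileScaler("q1").fit(X)
        q1 = np.percentile(X, 25, axis=0)
        q3 = np.percentile(X, 75, axis=0)
        np.testing.assert_allclose(scaler.transform(q1[None, :]).ravel(),
                                   0.0, atol=1e-12)
        np.testing.assert_allclose(scaler.transform(q3[None, :]).ravel(),
                                   1.0, atol=1e-12)

    def test_constant_column_scaled_to_zero(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        out = RobustQuantileScaler("q1").fit_transform(X)
        np.testing.assert_allclose(out[:, 1], 0.0)

    def test_refit_on_scaled_training_rows_is_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        once = RobustQuantileScaler("q1").fit_transform(X)
        twice = RobustQuantileScaler("q1").fit_transform(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_median_center_option(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        out = RobustQuantileScaler("median").fit_transform(X)
        np.testing.assert_allclose(out.ravel(), [-1.0, -0.5, 0, 0.5, 1.0])

    def test_robust_scale_wrapper(self, cohort_matrix):
        scaled = robust_scale(cohort_matrix.select(["af_score",
                                                    "n_switches"]))
        q1 = np.nanpercentile(scaled.data["af_score"], 25)
        assert q1 == pytest.approx(0.0, abs=1e-12)


class TestImputeMedian:
    def test_train_median_applied_to_test(self):
        train = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]])
        test = np.array([[np.nan, np.nan]])
        tr, te = impute_median(train, test)
        assert not np.isnan(tr).any()
        np.testing.assert_allclose(te, [[3.0, 5.0]])

    def test_all_nan_column_filled_with_zero(self):
        train = np.full((3, 1), np.nan)
        (tr,) = impute_median(train)
        np.testing.assert_allclose(tr, 0.0)


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_three_point_example(self):
        assert auc_roc([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc_roc([0.1, 0.2], [1, 1])

    def test_random_scores_near_half_large_n(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert auc_roc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @given(scores=st.lists(st.integers(min_value=0, max_value=4), min_size=2,
                           max_size=8),
           labels_seed=st.integers(min_value=0, max_value=2**16))
    def test_matches_brute_force_pair_counting(self, scores, labels_seed):
        rng = np.random.default_rng(labels_seed)
        labels = rng.integers(0, 2, len(scores))
        if len(set(labels.tolist())) < 2:
            return
        assert auc_roc(scores, labels) == \
            pytest.approx(brute_force_auc(scores, labels))


class TestSensitivitySpecificity:
    def test_all_correct(self):
        assert sensitivity_specificity([1, 0, 1, 0], [1, 0, 1, 0]) == \
            (1.0, 1.0)

    def test_all_predicted_positive(self):
        assert sensitivity_specificity([1, 1, 1], [1, 0, 1]) == (1.0, 0.0)

    def test_confusion_table_ratios(self):
        pred = [1, 1, 1, 0, 0, 0, 0, 0, 1, 1]
        lab = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        # TP=3 FN=1 TN=4 FP=2
        sens, spec = sensitivity_specificity(pred, lab)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(2 / 3)


class TestRfecv:
    def make_informative_matrix(self, seed, n=60, n_noise=8):
        rng = np.random.default_rng(seed)
        y = np.repeat([1, 0], [n // 2, n - n // 2])
        informative = np.column_stack([
            y * 2.0 + rng.normal(0, 0.8, n),
            -1.5 * y + rng.normal(0, 0.8, n),
        ])
        noise = rng.normal(size=(n, n_noise))
        X = np.column_stack([informative, noise])
        names = ["inf_a", "inf_b"] + [f"noise{i}" for i in range(n_noise)]
        return make_matrix(X, y, names)

    def test_informative_features_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            m = self.make_informative_matrix(seed)
            selected = rfecv_select(m, ClassifierConfig(C=1.0, penalty="l2"),
                                    seed=seed)
            hits += {"inf_a", "inf_b"} <= set(selected)
        assert hits >= 9  # both informative features kept in >=90% of seeds

    def test_single_feature_passthrough(self):
        m = self.make_informative_matrix(0).select(["inf_a"])
        assert rfecv_select(m, ClassifierConfig(), seed=0) == ["inf_a"]

    def test_degenerate_labels_rejected(self):
        m = self.make_informative_matrix(0)
        m.labels[:] = "CI"
        with pytest.raises(UndefinedMetricError):
            rfecv_select(m, ClassifierConfig(), seed=0)


class TestLopoStructure:
    def test_balanced_28_42_folds(self):
        y = np.repeat([1, 0], [28, 42])
        rng = np.random.default_rng(0)
        folds = list(iter_lopo_folds(y, rng))
        assert len(folds) == 28
        for test, train in folds:
            assert y[test].tolist() in ([1, 0], [0, 1])
            assert len(test) == 2
            assert (y[train] == 1).sum() == 27
            assert (y[train] == 0).sum() == 27
            assert set(test).isdisjoint(train)
            assert len(set(train.tolist())) == 54  # sampling w/o replacement

    def test_every_mci_tested_exactly_once_per_repeat(self):
        y = np.repeat([1, 0], [28, 42])
        rng = np.random.default_rng(1)
        tested = [test[0] for test, _ in iter_lopo_folds(y, rng)]
        assert sorted(tested) == list(range(28))


class TestLopoCv:
    def test_bit_reproducible(self, cohort_matrix):
        cfg = ClassifierConfig()
        r1 = lopo_cv(cohort_matrix, cfg, n_repeats=3, seed=42)
        r2 = lopo_cv(cohort_matrix, cfg, n_repeats=3, seed=42)
        assert (r1.auc, r1.sensitivity, r1.specificity) == \
            (r2.auc, r2.sensitivity, r2.specificity)

    def test_chance_model_near_fifty(self, cohort_matrix):
        rep = lopo_cv(cohort_matrix, n_repeats=300, seed=0, model="chance")
        assert rep.auc == pytest.approx(50.0, abs=3.0)

    def test_metrics_within_percent_range(self, cohort_matrix):
        rep = lopo_cv(cohort_matrix, ClassifierConfig(), n_repeats=3, seed=0)
        for v in (rep.auc, rep.sensitivity, rep.specificity):
            assert 0 <= v <= 100

    def test_invalid_repeats(self, cohort_matrix):
        with pytest.raises(ValidationError):
            lopo_cv(cohort_matrix, n_repeats=0, seed=0)

    def test_separable_features_beat_chance(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1, 0], [12, 16])
        X = np.column_stack([y * 3.0 + rng.normal(0, 1.0, 28),
                             rng.normal(size=28)])
        rep = lopo_cv(make_matrix(X, y), ClassifierConfig(C=1.0,
                                                          penalty="l2"),
                      n_repeats=10, seed=0)
        assert rep.auc > 75.0
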