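import itertools

import numpy as np
import pandas as pd
import pytest

from shockpred.classify import (
    BivariateResult,
    ClassifierConfig,
    CVConfig,
    accuracy_at_half,
    bivariate_screen,
    chi_squared_stat,
    make_smote_gbt_pipeline,
    repeated_stratified_cv,
    roc_auc,
    shock_index,
    train_classifier,
)
from shockpred.errors import ConfigError
from shockpred.matrix import FeatureMatrix, VariableMeta
from shockpred.rebalance import ResampleConfig


def brute_force_auc(scores, labels):
    """Oracle: exhaustive positive-negative pair counting."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBivariateScreen:
    def _matrix(self, data, metas):
        df = pd.DataFrame(data, index=pd.Index(range(len(next(iter(data.values())))),
                                               name="subject_id"))
        return FeatureMatrix(df, metas)

    def test_chi_squared_textbook_formula(self):
        # [[10,20],[20,10]]: expected 15 everywhere -> sum (O-E)^2/E = 20/3
        table = np.array([[10, 20], [20, 10]])
        expected = table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :] / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        stat, _ = chi_squared_stat(table)
        assert stat == pytest.approx(oracle)
        assert stat == pytest.approx(20 / 3)

    def test_categorical_gets_chi_squared(self):
        rng = np.random.default_rng(0)
        n = 200
        labels = np.array([0] * 100 + [1] * 100)
        cat = np.where(rng.random(n) < 0.5, "a", "b")
        m = self._matrix({"c": cat},
                         [VariableMeta("c", "categorical", levels=("a", "b"))])
        results, _ = bivariate_screen(m, labels)
        assert results[0].test == "chi-squared"

    def test_null_continuous_p_near_one(self):
        x = np.concatenate([np.arange(50.0), np.arange(50.0)])
        labels = np.array([0] * 50 + [1] * 50)
        m = self._matrix({"v": x}, [VariableMeta("v", "continuous")])
        results, _ = bivariate_screen(m, labels)
        assert results[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert results[0].p > 0.99

    def test_large_shift_significant(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(5, 1, 100)])
        labels = np.array([0] * 100 + [1] * 100)
        m = self._matrix({"v": x}, [VariableMeta("v", "continuous")])
        results, _ = bivariate_screen(m, labels)
        assert results[0].p < 0.001
        assert results[0].test in ("t", "mann-whitney")

    def test_skewed_variable_uses_mann_whitney(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 1.5, 300))  # heavily skewed
        labels = rng.integers(0, 2, 300)
        m = self._matrix({"v": x}, [VariableMeta("v", "continuous")])
        results, _ = bivariate_screen(m, labels)
        assert results[0].test == "mann-whitney"

    def test_constant_variable_skipped(self):
        m = self._matrix({"v": np.ones(20)}, [VariableMeta("v", "continuous")])
        results, skipped = bivariate_screen(m, np.array([0, 1] * 10))
        assert results == [] and skipped == ["v"]


class TestShockIndex:
    def test_simple_ratio(self):
        assert shock_index(80, 100) == pytest.approx(0.8)

    def test_zero_hr(self):
        assert shock_index(0, 100) == 0.0

    def test_ratio_of_means_differs_from_mean_of_ratios(self):
        # HR 94.1 / SBP 108.9 = 0.864, a per-subject mean of ratios can be 0.90
        assert shock_index(94.1, 108.9) == pytest.approx(0.864, abs=5e-4)

    def test_non_positive_bp_missing(self):
        out = shock_index([80.0, 90.0], [0.0, -5.0])
        assert np.isnan(out).all()


class TestTrainClassifier:
    def test_separable_data_perfect_training_auc(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (100, 2)), rng.normal(5, 0.3, (100, 2))])
        y = np.array([0] * 100 + [1] * 100)
        clf = train_classifier(X, y, ClassifierConfig(seed=0))
        _, _, auc = roc_auc(clf.predict_proba(X)[:, 1], y)
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            train_classifier(np.zeros((10, 2)), np.zeros(10, dtype=int),
                             ClassifierConfig())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = rng.integers(0, 2, 80)
        p1 = train_classifier(X, y, ClassifierConfig(seed=5)).predict_proba(X)
        p2 = train_classifier(X, y, ClassifierConfig(seed=5)).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            ClassifierConfig(n_estimators=0)
        with pytest.raises(ConfigError):
            ClassifierConfig(num_leaves=1)


class TestRocAuc:
    def test_perfect_ranking(self):
        _, _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        _, _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_hand_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_exhaustive_small_alphabet_oracle(self):
        # all score vectors of length <= 6 over a 3-value alphabet, plus a
        # random batch at length <= 10
        alphabet = [0.0, 0.5, 1.0]
        for n in (2, 3, 4, 5, 6):
            labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
            if labels.sum() == 0:
                continue
            for scores in itertools.product(alphabet, repeat=n):
                _, _, auc = roc_auc(np.array(scores), labels)
                assert auc == pytest.approx(brute_force_auc(scores, labels))
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        _, _, a1 = roc_auc(scores, labels)
        _, _, a2 = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_one_class_rejected(self):
        with pytest.raises(ConfigError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.random(n).round(1)  # force ties
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores))


def _null_pipeline(X_tr, y_tr, X_val, rng):
    return rng.random(len(X_val))


class TestRepeatedStratifiedCV:
    def test_run_count(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = np.array([0] * 40 + [1] * 20)
        report = repeated_stratified_cv({"d0": X}, y,
                                        CVConfig(n_splits=5, n_repeats=10, seed=0),
                                        _null_pipeline)
        assert len(report.runs) == 50

    def test_stratification_within_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(103, 2))
        y = np.array([0] * 80 + [1] * 23)
        n_splits = 5
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=1)
        for _, va in skf.split(X, y):
            n1 = y[va].sum()
            assert abs(n1 - 23 / n_splits) <= 1

    def test_fold_seeds_shared_across_datasets(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 2))
        y = np.array([0] * 28 + [1] * 12)
        calls = []

        def spy(X_tr, y_tr, X_val, inner_rng):
            calls.append(X_val.sum())
            return np.zeros(len(X_val)) + 0.5

        repeated_stratified_cv({"a": X, "b": X}, y,
                               CVConfig(n_splits=4, n_repeats=2, seed=3), spy)
        per_ds = len(calls) // 2
        assert np.allclose(calls[:per_ds], calls[per_ds:])  # identical folds

    def test_minority_smaller_than_splits_rejected(self):
        X = np.zeros((20, 2))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ConfigError):
            repeated_stratified_cv({"d": X}, y, CVConfig(n_splits=5, n_repeats=1),
                                   _null_pipeline)

    def test_null_features_auc_near_half(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 4))
        y = np.array([0] * 80 + [1] * 40)
        report = repeated_stratified_cv({"d": X}, y,
                                        CVConfig(n_splits=4, n_repeats=5, seed=4),
                                        _null_pipeline)
        assert abs(report.runs["auc"].mean() - 0.5) < 0.1

    def test_summary_ci_ordering(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 2))
        y = np.array([0] * 30 + [1] * 20)
        report = repeated_stratified_cv({"d": X}, y,
                                        CVConfig(n_splits=3, n_repeats=3, seed=5),
                                        _null_pipeline)
        s = report.summary()
        for metric in ("auc", "accuracy"):
            lo, hi = s[metric]["ci95"]
            assert lo <= s[metric]["mean"] <= hi
            assert s[metric]["sd"] >= 0

    def test_no_resampling_leakage(self):
        # validation rows never appear as originals or SMOTE parents in the
        # training material of their own fold
        from shockpred.rebalance import smote_enn

        rng = np.random.default_rng(13)
        X = rng.normal(size=(60, 3))
        X[40:] += 2.0
        y = np.array([0] * 40 + [1] * 20)
        leaks = []

        def tracked(X_tr, y_tr, X_val, inner_rng):
            rs = smote_enn(X_tr, y_tr, ResampleConfig(seed=0), rng=inner_rng)
            train_rows = {tuple(np.round(r, 9)) for r in rs.X[rs.provenance == "original"]}
            parent_rows = {tuple(np.round(X_tr[p], 9))
                           for pair in rs.parents if pair[0] >= 0
                           for p in pair}
            val_rows = {tuple(np.round(r, 9)) for r in X_val}
            leaks.append(val_rows & (train_rows | parent_rows))
            return np.zeros(len(X_val)) + 0.5

        repeated_stratified_cv({"d": X}, y, CVConfig(n_splits=4, n_repeats=2, seed=6),
                               tracked)
        assert all(len(leak) == 0 for leak in leaks)

    def test_smote_gbt_pipeline_runs(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(2, 1, (20, 3))])
        y = np.array([0] * 60 + [1] * 20)
        pipeline = make_smote_gbt_pipeline(ResampleConfig(seed=0),
                                           ClassifierConfig(n_estimators=20))
        report = repeated_stratified_cv({"d": X}, y,
                                        CVConfig(n_splits=4, n_repeats=1, seed=7),
                                        pipeline)
        assert len(report.runs) == 4
        assert report.runs["auc"].between(0, 1).all()
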