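"""Random-forest CV protocol, ridge with unpenalized covariates, AUC and
attribution-vs-ridge concordance."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from micromet import classify, ev


class TestAuc:
    def test_perfect_separation(self):
        assert classify.roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_enumerated_example(self):
        assert classify.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_label_flip_symmetry(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert classify.roc_auc(s, y) == pytest.approx(1 - classify.roc_auc(s, 1 - y))

    def test_ties_count_half(self):
        assert classify.roc_auc([1.0, 1.0], [0, 1]) == pytest.approx(0.5)

    def test_matches_trapezoidal_reference(self, rng):
        for _ in range(20):
            s = rng.normal(size=60)
            s[rng.integers(0, 60, 10)] = 0.0  # inject ties
            y = rng.integers(0, 2, 60)
            y[:2] = [0, 1]
            assert classify.roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-9)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            classify.roc_auc([1, 2], [1, 1])


class TestRfClassifier:
    def test_planted_signal_reaches_high_auc(self, rng):
        n = 200
        X = rng.normal(size=(n, 10))
        y = rng.integers(0, 2, n)
        X[y == 1, 0] += 2.0
        X[y == 1, 1] += 2.0
        cv, model = classify.rf_cv_classifier(X, y, n_trees=150, folds=5, repeats=1, seed=1)
        assert cv.mean_metric >= 0.9
        assert len(cv.fold_metrics) == 5
        assert model.n_estimators == 150

    def test_null_auc_not_inflated_by_upsampling(self, rng):
        aucs = []
        for seed in range(6):
            X = rng.normal(size=(150, 10))
            y = (rng.random(150) < 0.3).astype(int)  # imbalanced null
            if y.sum() < 5 or y.sum() > 145:
                continue
            cv, _ = classify.rf_cv_classifier(X, y, n_trees=100, folds=5, repeats=1, seed=seed)
            aucs.append(cv.mean_metric)
        assert abs(np.mean(aucs) - 0.5) <= 0.07

    def test_test_folds_keep_raw_class_proportions(self, rng):
        # upsampling must stay inside training folds: the recorded test-fold
        # sizes have to match a plain stratified split of the raw data
        X = rng.normal(size=(100, 4))
        y = np.array([0] * 70 + [1] * 30)
        cv, _ = classify.rf_cv_classifier(X, y, n_trees=20, folds=5, repeats=1, seed=2)
        assert sorted(cv.fold_sizes) == [20] * 5  # all 100 raw samples, once each

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            classify.rf_cv_classifier(rng.normal(size=(40, 3)), np.zeros(40), folds=2)


class TestRfRegressor:
    def test_noiseless_linear_signal(self, rng):
        X = rng.normal(size=(500, 4))
        y = 2 * X[:, 0] - X[:, 1]
        cv, _ = classify.rf_cv_regressor(X, y, n_trees=200, folds=5, repeats=1, seed=3)
        assert cv.mean_metric >= 0.9

    def test_null_target_gives_no_r2(self, rng):
        X = rng.normal(size=(200, 4))
        y = rng.normal(size=200)
        cv, _ = classify.rf_cv_regressor(X, y, n_trees=100, folds=5, repeats=1, seed=4)
        assert cv.mean_metric <= 0.05

    def test_first_repeat_reproduced_when_repeats_grow(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + rng.normal(size=100)
        cv1, _ = classify.rf_cv_regressor(X, y, n_trees=50, folds=5, repeats=1, seed=5)
        cv2, _ = classify.rf_cv_regressor(X, y, n_trees=50, folds=5, repeats=2, seed=5)
        assert np.allclose(cv1.fold_metrics, cv2.fold_metrics[:5])

    def test_fold_mean_agrees_with_explained_variance(self, rng):
        # the aggregate must be the mean of per-fold 1 - SSE/SST values
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + rng.normal(size=100)
        cv, _ = classify.rf_cv_regressor(X, y, n_trees=50, folds=5, repeats=2, seed=6)
        assert cv.mean_metric == pytest.approx(cv.fold_metrics.mean(), abs=1e-12)

    def test_constant_target_raises(self, rng):
        with pytest.raises(ValueError):
            classify.rf_cv_regressor(rng.normal(size=(50, 2)), np.ones(50))


class TestRidge:
    def test_tiny_penalty_recovers_ols(self, rng):
        n, p = 50, 3
        X = rng.normal(size=(n, p))
        Z = rng.normal(size=(n, 2))
        y = X @ [1.0, -2.0, 0.5] + Z @ [0.3, 0.7] + 0.01 * rng.normal(size=n)
        bx, bz, b0 = classify._ridge_solve(X, Z, y, 1e-10)
        D = np.column_stack([np.ones(n), Z, X])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert np.allclose(bx, ols[3:], atol=1e-6)
        assert np.allclose(bz, ols[1:3], atol=1e-6)

    def test_huge_penalty_kills_features_not_covariates(self, rng):
        n = 200
        X = rng.normal(size=(n, 4))
        Z = rng.normal(size=(n, 1))
        y = 2 * Z[:, 0] + X[:, 0] + rng.normal(size=n)
        bx, bz, _ = classify._ridge_solve(X, Z, y, 1e9)
        assert np.abs(bx).max() < 1e-4
        assert bz[0] == pytest.approx(2.0, abs=0.2)

    def test_planted_coefficients_recovered(self, rng):
        n = 1000
        X = rng.normal(size=(n, 5))
        Z = rng.normal(size=(n, 2))
        y = 2 * X[:, 0] - X[:, 1] + rng.normal(size=n)
        res = classify.ridge_adjusted(X, y, Z, seed=7)
        assert res.coefficients[0] > 0 > res.coefficients[1]
        assert np.argsort(-np.abs(res.coefficients))[0] == 0
        assert res.penalty > 0

    def test_rank_deficient_covariates_raise(self, rng):
        X = rng.normal(size=(50, 3))
        Z = np.ones((50, 2))  # collinear with the intercept
        with pytest.raises(ValueError, match="covariates"):
            classify.ridge_adjusted(X, rng.normal(size=50), Z)


class TestConcordance:
    def test_identical_vectors(self):
        out = classify.importance_concordance([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            classify.importance_concordance([1, 2, 3, 4, 5], [1, 2, 3])

    def test_null_vectors_rarely_correlate(self, rng):
        good = 0
        for _ in range(10):
            out = classify.importance_concordance(
                rng.normal(size=100), rng.normal(size=100)
            )
            good += abs(out["pearson_r"]) < 0.3
        assert good >= 9

    def test_linear_data_concordance_between_shap_and_ridge(self, rng):
        from micromet import attribution

        n, p = 2000, 8
        X = rng.normal(size=(n, p))
        beta = np.array([2.0, -1.5, 1.0, -0.5, 0.25, 0.0, 0.0, 0.0])
        y = X @ beta + rng.normal(size=n)
        model = ev.fit_gbdt(X, y, spec=ev.GBDTSpec(n_search=3, num_boost_round=150), seed=8)
        am = attribution.attribution_values(model, X)
        signed = attribution.signed_importance(am, X)
        ridge = classify.ridge_adjusted(X, y, rng.normal(size=(n, 1)), seed=9)
        out = classify.importance_concordance(signed, ridge.coefficients)
        assert out["pearson_r"] >= 0.8
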