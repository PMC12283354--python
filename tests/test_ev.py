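"""Explained-variance machinery: R2, out-of-fold contracts, q-values,
relative power guards and cross-cohort replication."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from micromet import ev
from micromet.dataio import MetaboliteMatrix


class TestExplainedVariance:
    @pytest.mark.parametrize(
        "y,yhat,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [2.5] * 4, 0.0),
            ([1, 2, 3, 4], [1, 2, 3, 5], 0.8),
        ],
    )
    def test_known_values(self, y, yhat, expected):
        assert ev.explained_variance(y, yhat) == pytest.approx(expected)

    def test_matches_two_pass_brute_force(self, rng):
        for _ in range(20):
            y = rng.normal(size=40)
            yhat = rng.normal(size=40)
            sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
            mean = sum(y) / len(y)
            sst = sum((a - mean) ** 2 for a in y)
            assert abs(ev.explained_variance(y, yhat) - (1 - sse / sst)) < 1e-12

    def test_constant_target_is_nan(self):
        assert np.isnan(ev.explained_variance([1.0] * 5, [1, 2, 3, 4, 5]))


class TestOofPredict:
    def test_strong_linear_signal_is_predicted(self, rng):
        X = rng.normal(size=(500, 5))
        y = 2.0 * X[:, 0] + 0.1 * rng.normal(size=500)
        spec = ev.GBDTSpec(n_search=1, num_boost_round=150,
                           fixed_params={"num_leaves": 8, "learning_rate": 0.1})
        pred = ev.oof_predict(X, y, k=5, spec=spec, seed=1)
        assert np.corrcoef(y, pred)[0, 1] > 0.95

    def test_null_target_gives_no_out_of_sample_r2(self, rng):
        X = rng.normal(size=(500, 5))
        y = rng.normal(size=500)
        pred = ev.oof_predict(X, y, k=5, spec=ev.GBDTSpec.fast(), seed=2)
        assert ev.explained_variance(y, pred) <= 0.05

    def test_leave_one_out_is_row_order_invariant(self, rng):
        n = 20
        X = rng.normal(size=(n, 3))
        y = X[:, 0] + rng.normal(size=n)
        spec = ev.GBDTSpec.fast()
        base = ev.oof_predict(X, y, k=n, spec=spec, seed=3)
        perm = rng.permutation(n)
        permuted = ev.oof_predict(X[perm], y[perm], k=n, spec=spec, seed=3)
        unperm = np.empty(n)
        unperm[perm] = permuted
        assert np.allclose(base, unperm, atol=1e-8)

    def test_too_few_samples_raise(self, rng):
        with pytest.raises(ValueError, match="2k"):
            ev.oof_predict(rng.normal(size=(8, 2)), rng.normal(size=8), k=5)

    def test_constant_target_warns_and_returns_constant(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            pred = ev.oof_predict(rng.normal(size=(20, 2)), np.ones(20), k=5)
        assert (pred == 1.0).all()

    def test_added_noise_columns_do_not_inflate_null_r2(self, rng):
        r2_small, r2_big = [], []
        for i in range(8):
            Xs = rng.normal(size=(200, 5))
            Xb = np.hstack([Xs, rng.normal(size=(200, 30))])
            y = rng.normal(size=200)
            spec = ev.GBDTSpec.fast()
            r2_small.append(ev.explained_variance(y, ev.oof_predict(Xs, y, 5, spec, seed=i)))
            r2_big.append(ev.explained_variance(y, ev.oof_predict(Xb, y, 5, spec, seed=i)))
        assert np.median(r2_big) <= np.median(r2_small) + 0.05


class TestEvBootstrap:
    def test_same_seed_reproduces_result_exactly(self, rng):
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + rng.normal(size=60)
        kwargs = dict(B=30, k=5, spec=ev.GBDTSpec.fast(), seed=11, n_perm=4)
        with pytest.warns(UserWarning):
            r1 = ev.ev_bootstrap(X, y, **kwargs)
        with pytest.warns(UserWarning):
            r2 = ev.ev_bootstrap(X, y, **kwargs)
        assert r1.r2 == r2.r2 and r1.p == r2.p
        assert np.array_equal(r1.boot_r2, r2.boot_r2)

    def test_planted_signal_is_detected(self, rng):
        X = rng.normal(size=(300, 10))
        y = np.sqrt(0.5) * X[:, 0] + np.sqrt(0.5) * rng.normal(size=300)
        res = ev.ev_bootstrap(X, y, B=50, k=5, spec=ev.GBDTSpec.fast(), seed=12, n_perm=8)
        assert res.r2 > 0.2
        assert res.p < 0.01
        assert res.ci_low <= res.r2 <= res.ci_high


class TestQValues:
    def test_all_ones_stay_ones(self):
        q, _ = ev.compute_qvalues(np.ones(20))
        assert (q == 1).all()

    def test_bh_arithmetic_with_pi0_one(self):
        q, _ = ev.compute_qvalues(np.array([0.001, 0.5]), pi0=1.0)
        assert np.allclose(q, [0.002, 0.5])

    def test_equals_benjamini_hochberg_at_pi0_one(self, rng):
        for _ in range(10):
            p = rng.uniform(size=200)
            q, _ = ev.compute_qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.abs(q - bh).max() < 1e-12

    def test_null_uniform_p_yield_almost_no_discoveries(self, rng):
        p = rng.uniform(size=1000)
        q, _ = ev.compute_qvalues(p)
        assert (q < 0.1).mean() < 0.02

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ev.compute_qvalues(np.array([0.5, 1.5]))

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=500)
        q, _ = ev.compute_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestRelativePower:
    def test_all_noise_metabolome_is_flagged_uninformative(self):
        from micromet import synthgen

        bundle = synthgen.gen_feature_bundle(60, 4, 12, 5, seed=21)
        metab, _ = synthgen.gen_metabolite_matrix(
            bundle, {f"m{i}": synthgen.MetaboliteSignal() for i in range(6)}, seed=22
        )
        std = (metab - metab.mean()) / metab.std(ddof=1)
        res = ev.relative_power(
            bundle, MetaboliteMatrix(std, state="preprocessed"),
            spec=ev.GBDTSpec.fast(), seed=23,
        )
        assert res.uninformative
        assert all(np.isnan(v) for v in res.shares.values())

    def test_single_driving_group_dominates(self):
        from micromet import synthgen

        bundle = synthgen.gen_feature_bundle(400, 8, 12, 5, seed=24)
        plan = {f"m{i}": synthgen.MetaboliteSignal(clinical=0.5, n_active=3) for i in range(10)}
        metab, _ = synthgen.gen_metabolite_matrix(bundle, plan, seed=25)
        std = (metab - metab.mean()) / metab.std(ddof=1)
        res = ev.relative_power(
            bundle, MetaboliteMatrix(std, state="preprocessed"),
            spec=ev.GBDTSpec.fast(), seed=26,
        )
        assert not res.uninformative
        assert res.shares["clinical"] > 0.8
        assert abs(sum(res.shares.values()) - 1) < 1e-9


class TestReplicationCompare:
    def test_gross_outlier_is_flagged(self):
        a = np.linspace(0, 1, 30)
        b = 2 * a + 0.01 * np.sin(np.arange(30))  # slight jitter, no exact fit
        b[7] += 3.0
        res = ev.replication_compare(a, b)
        assert res.outliers[7]
        assert res.outliers.sum() <= 3

    def test_exact_line_has_no_influential_points(self):
        a = np.linspace(0, 1, 15)
        res = ev.replication_compare(a, 3 * a + 1)
        assert np.allclose(res.cooks_d, 0)
        assert not res.outliers.any()

    def test_infinite_factor_disables_flags(self, rng):
        a = rng.normal(size=20)
        res = ev.replication_compare(a, a + rng.normal(size=20), factor=np.inf)
        assert not res.outliers.any()

    def test_short_input_raises(self):
        with pytest.raises(ValueError, match="10"):
            ev.replication_compare([1, 2], [3, 4])
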