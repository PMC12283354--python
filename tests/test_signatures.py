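"""Differential calling, odds ratios, overlaps, proportion tests, repeated
measures and response clustering."""

import numpy as np
import pandas as pd
import pytest

from micromet import signatures, synthgen


class TestWilcoxon:
    def test_separated_small_groups_exact_p(self):
        w, p, d = signatures.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)
        assert d == -1

    def test_identical_multisets(self):
        _, p, d = signatures.wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)
        assert d == 0

    def test_exact_matches_enumeration_for_all_small_sizes(self):
        from micromet.experiments import wilcoxon_enumeration_check

        res = wilcoxon_enumeration_check(max_m=5, max_n=5)
        assert res["max_abs_diff"] < 1e-12


class TestDifferentialCalling:
    def _dataset(self, seed, n_per=100, shift=1.0, n_metab=30, n_planted=3):
        rng = np.random.default_rng(seed)
        ids = [f"S{i}" for i in range(2 * n_per)]
        groups = np.array(["T2D"] * n_per + ["NGT"] * n_per)
        vals = rng.normal(size=(2 * n_per, n_metab))
        vals[: n_per, :n_planted] += shift
        metab = pd.DataFrame(vals, index=ids, columns=[f"m{i}" for i in range(n_metab)])
        meta = synthgen.SampleMetadata(
            pd.DataFrame(
                {"age": 55.0, "sex": 0.0, "bmi": 27.0, "group": groups}, index=ids
            )
        )
        return metab, meta

    def test_planted_shift_is_called_significant(self):
        hits = 0
        for seed in range(20):
            metab, meta = self._dataset(seed)
            res = signatures.differential_metabolites(metab, meta, ("T2D", "NGT"))
            planted = res[res["metabolite_id"].isin(["m0", "m1", "m2"])]
            hits += (planted["q"] < 0.1).all()
        assert hits >= 19

    def test_null_fdr_is_controlled(self):
        bad = 0
        for seed in range(10):
            metab, meta = self._dataset(seed + 100, shift=0.0, n_metab=200, n_planted=0)
            res = signatures.differential_metabolites(metab, meta, ("T2D", "NGT"))
            if (res["q"] < 0.1).mean() > 0.15:
                bad += 1
        assert bad <= 1

    def test_empty_group_raises(self):
        metab, meta = self._dataset(0)
        with pytest.raises(ValueError):
            signatures.differential_metabolites(metab, meta, ("IFG", "NGT"))

    def test_consistent_signatures_require_same_direction(self):
        disc = pd.DataFrame(
            {
                "metabolite_id": ["a", "b", "c"],
                "comparison": ["T2D_vs_NGT"] * 3,
                "effect_direction": [1, 1, -1],
                "significant": [True, True, True],
            }
        )
        val = disc.copy()
        val.loc[1, "effect_direction"] = -1  # direction flips in validation
        val.loc[2, "significant"] = False
        out = signatures.consistent_signatures(disc, val)
        assert list(out["metabolite_id"]) == ["a"]


class TestOddsRatio:
    def test_2x2_cross_product_identity(self):
        y = np.repeat([1, 1, 0, 0], [10, 20, 30, 40])
        x = np.repeat([1, 0, 1, 0], [10, 20, 30, 40])
        res = signatures.adjusted_odds_ratio(y, x)
        assert res.or_value == pytest.approx(10 * 40 / (20 * 30), abs=1e-6)

    def test_null_metabolite_or_near_one_with_covering_ci(self, rng):
        covered = 0
        ors = []
        for _ in range(20):
            n = 2000
            age = rng.uniform(50, 64, n)
            sex = rng.integers(0, 2, n).astype(float)
            logit = -1.0 + 0.03 * (age - 57)
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            met = rng.normal(size=n)
            res = signatures.adjusted_odds_ratio(y, met, age, sex)
            ors.append(res.or_value)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 17
        assert np.mean(ors) == pytest.approx(1.0, abs=0.05)

    def test_duplicated_covariate_raises(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        met = rng.normal(size=100)
        with pytest.raises(ValueError, match="rank"):
            signatures.adjusted_odds_ratio(y, met, met, None)

    def test_perfect_separation_is_flagged(self):
        y = np.repeat([0.0, 1.0], 20)
        met = np.concatenate([np.zeros(20), np.ones(20) * 5])
        res = signatures.adjusted_odds_ratio(y, met)
        assert res.separation
        assert np.isinf(res.ci_high)


class TestOverlap:
    def test_two_set_regions(self):
        out = signatures.overlap_summary({"A": {"a", "b"}, "B": {"b", "c"}})
        counts = dict(zip(out["region"], out["count"]))
        assert counts == {"A": 1, "A&B": 1, "B": 1}

    def test_identical_sets_fully_intersect(self):
        out = signatures.overlap_summary({"A": {1, 2}, "B": {1, 2}})
        assert dict(zip(out["region"], out["count"])) == {"A&B": 2}

    def test_three_sets_match_brute_force(self, rng):
        universe = list(range(6))
        sets = {n: set(rng.choice(universe, rng.integers(1, 6), replace=False).tolist())
                for n in "ABC"}
        out = signatures.overlap_summary(sets)
        total = out["count"].sum()
        assert total == len(set().union(*sets.values()))
        for _, row in out.iterrows():
            inside = set(row["region"].split("&"))
            for member in row["members"]:
                m = int(member)
                assert {n for n in "ABC" if m in sets[n]} == inside


class TestProportionTest:
    def test_hand_computed_chi_squared(self):
        chi2, dof, p = signatures.proportion_test([[30, 70], [10, 90]])
        assert chi2 == pytest.approx(12.5, abs=1e-10)
        assert dof == 1

    def test_equal_rows_give_zero(self):
        chi2, _, p = signatures.proportion_test([[5, 5], [5, 5]])
        assert chi2 == 0 and p == pytest.approx(1.0)

    def test_matches_direct_sum_formula(self, rng):
        table = rng.integers(5, 50, size=(2, 4)).astype(float)
        chi2, dof, _ = signatures.proportion_test(table)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert chi2 == pytest.approx(((table - exp) ** 2 / exp).sum(), abs=1e-10)
        assert dof == 3

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            signatures.proportion_test([[0, 5], [0, 7]])


class TestRepeatedMeasures:
    def test_flat_profiles_give_f_zero(self):
        vals = np.tile([[1.0], [2.0], [5.0]], (1, 4))
        f, (df1, df2), p = signatures.repeated_measures_anova(vals)
        assert f == 0 and p == pytest.approx(1.0)
        assert (df1, df2) == (3, 6)

    def test_matches_hand_computed_sums_of_squares(self, rng):
        v = rng.normal(size=(4, 3))
        f, (df1, df2), p = signatures.repeated_measures_anova(v)
        # independent decomposition
        grand = v.mean()
        ss_time = 4 * ((v.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((v.mean(1) - grand) ** 2).sum()
        ss_err = ((v - grand) ** 2).sum() - ss_time - ss_subj
        assert f == pytest.approx((ss_time / 2) / (ss_err / 6), abs=1e-10)
        assert (df1, df2) == (2, 6)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        v = rng.normal(size=(6, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 3),
                "time": np.tile(np.arange(3), 6),
                "value": v.ravel(),
            }
        )
        ref = AnovaRM(long, "value", "subject", within=["time"]).fit()
        f, _, p = signatures.repeated_measures_anova(v)
        assert f == pytest.approx(float(ref.anova_table["F Value"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]), abs=1e-8)

    def test_subject_offset_leaves_f_unchanged(self, rng):
        v = rng.normal(size=(5, 3))
        f1, _, _ = signatures.repeated_measures_anova(v)
        v2 = v.copy()
        v2[2] += 100.0
        f2, _, _ = signatures.repeated_measures_anova(v2)
        assert f1 == pytest.approx(f2, abs=1e-8)

    def test_missing_cells_reduce_to_complete_cases(self, rng):
        v = rng.normal(size=(6, 3))
        v2 = v.copy()
        v2[0, 1] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            f2, _, _ = signatures.repeated_measures_anova(v2)
        f1, _, _ = signatures.repeated_measures_anova(v[1:])
        assert f1 == pytest.approx(f2)


class TestClusterResponses:
    def _blocks(self):
        rows = [[1, 1, 1, 0]] * 5 + [[-1, -1, 0, 1]] * 4
        return pd.DataFrame(rows, index=[f"m{i}" for i in range(9)],
                            columns=list("abcd"))

    def test_two_separated_blocks_are_recovered(self):
        labels = signatures.cluster_responses(self._blocks(), k=2)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_identical_rows_collapse_regardless_of_k(self):
        eff = pd.DataFrame([[1, 0]] * 6, index=[f"m{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="reduced"):
            labels = signatures.cluster_responses(eff, k=4)
        assert labels.nunique() == 1

    def test_row_order_invariance(self, rng):
        eff = self._blocks()
        perm = rng.permutation(len(eff))
        labels = signatures.cluster_responses(eff, k=2)
        labels_perm = signatures.cluster_responses(eff.iloc[perm], k=2)
        # same partition (up to label names)
        for i in range(len(eff)):
            for j in range(len(eff)):
                a = labels.iloc[i] == labels.iloc[j]
                b = labels_perm.loc[eff.index[i]] == labels_perm.loc[eff.index[j]]
                assert a == b

    def test_constant_column_invariance(self):
        eff = self._blocks()
        labels1 = signatures.cluster_responses(eff, k=2)
        eff2 = eff.assign(const=1.0)
        labels2 = signatures.cluster_responses(eff2, k=2)
        assert (labels1 == labels2).all()
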