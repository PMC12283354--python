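"""Shapley attribution: local accuracy, a brute-force two-feature oracle,
pair selection, bi-network construction and centrality."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from micromet import attribution, ev


def _tree_conditional_expectation(tree, x, known):
    """E[f(X) | X_known = x_known] for one dumped LightGBM tree, taking
    cover-weighted averages over branches of unknown features."""

    def rec(node):
        if "leaf_value" in node:
            return node["leaf_value"]
        f = node["split_feature"]
        if f in known:
            go_left = x[f] <= node["threshold"]
            return rec(node["left_child"] if go_left else node["right_child"])
        lc = node["left_child"].get("internal_count", node["left_child"].get("leaf_count"))
        rc = node["right_child"].get("internal_count", node["right_child"].get("leaf_count"))
        tot = lc + rc
        return (lc * rec(node["left_child"]) + rc * rec(node["right_child"])) / tot

    return rec(tree["tree_structure"])


def _brute_force_shap_2feat(booster, x):
    """Exact Shapley values for a two-feature model via coalition enumeration
    with the path-dependent (cover-weighted) value function."""
    dump = booster.dump_model()
    trees = dump["tree_info"]

    def v(known):
        return sum(_tree_conditional_expectation(t, x, known) for t in trees)

    phi = []
    for i in (0, 1):
        other = 1 - i
        phi_i = 0.5 * (v({i}) - v(set())) + 0.5 * (v({0, 1}) - v({other}))
        phi.append(phi_i)
    return np.array(phi)


class TestAttributionValues:
    def test_single_stump_attributes_everything_to_the_split_feature(self, rng):
        X = rng.normal(size=(200, 3))
        y = np.where(X[:, 1] > 0, 2.0, -2.0)
        import lightgbm as lgb

        ds = lgb.Dataset(X, label=y, params={"verbosity": -1})
        booster = lgb.train(
            {"objective": "regression", "num_leaves": 2, "learning_rate": 1.0,
             "verbosity": -1, "num_threads": 1, "min_child_samples": 10, "seed": 1},
            ds, num_boost_round=1,
        )
        am = attribution.attribution_values(booster, X)
        pred = booster.predict(X)
        assert np.allclose(am.phi[:, 1], pred - am.base_value, atol=1e-9)
        assert np.allclose(am.phi[:, [0, 2]], 0)

    def test_matches_brute_force_two_feature_shapley(self, rng):
        import lightgbm as lgb

        X = rng.normal(size=(300, 2))
        y = X[:, 0] * X[:, 1] + X[:, 0] + rng.normal(size=300) * 0.1
        ds = lgb.Dataset(X, label=y, params={"verbosity": -1})
        booster = lgb.train(
            {"objective": "regression", "num_leaves": 4, "learning_rate": 0.3,
             "verbosity": -1, "num_threads": 1, "min_child_samples": 20, "seed": 2},
            ds, num_boost_round=5,
        )
        am = attribution.attribution_values(booster, X[:10])
        for i in range(10):
            oracle = _brute_force_shap_2feat(booster, X[i])
            assert np.allclose(am.phi[i], oracle, atol=1e-9)

    def test_local_accuracy_holds(self, small_bundle, small_metabolites):
        metab, _ = small_metabolites
        X = ev.assemble_design(small_bundle)["microbiome"]
        model = ev.fit_gbdt(X, metab["sig_micro"].to_numpy(), spec=ev.GBDTSpec(n_search=2), seed=3)
        am = attribution.attribution_values(model, X)
        assert am.local_accuracy_error() < 1e-6

    def test_feature_mismatch_raises(self, rng):
        import lightgbm as lgb

        X = rng.normal(size=(50, 3))
        ds = lgb.Dataset(X, label=rng.normal(size=50), params={"verbosity": -1})
        booster = lgb.train({"objective": "regression", "verbosity": -1, "num_leaves": 4,
                             "min_child_samples": 5}, ds, num_boost_round=2)
        with pytest.raises(ValueError, match="features"):
            attribution.attribution_values(booster, X[:, :2])


class TestAggregation:
    @pytest.mark.parametrize(
        "col,score,sign", [([0.0, 0.0], 0.0, 0), ([1.0, -1.0], 1.0, 0), ([2.0, 4.0], 3.0, 1)]
    )
    def test_score_and_sign(self, col, score, sign):
        am = attribution.AttributionMatrix(
            "m", 0.0, np.array(col)[:, None], ["f"], np.array(col)
        )
        agg = attribution.aggregate_attribution(am)
        assert agg.loc["f", "score"] == pytest.approx(score)
        assert agg.loc["f", "sign"] == sign


class TestTopPairs:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["mgs_id", "metabolite_id", "score", "sign"])

    def test_takes_largest_scores(self):
        scores = self._frame([("a", "m1", 0.5, 1), ("b", "m1", 0.4, 1), ("a", "m2", 0.3, 1)])
        top = attribution.select_top_pairs(scores, K=2)
        assert list(zip(top["mgs_id"], top["metabolite_id"])) == [("a", "m1"), ("b", "m1")]

    def test_ties_break_lexicographically(self):
        scores = self._frame(
            [("b", "m1", 1.0, 1), ("a", "m2", 1.0, 1), ("a", "m1", 1.0, 1)]
        )
        top = attribution.select_top_pairs(scores, K=2)
        assert list(zip(top["mgs_id"], top["metabolite_id"])) == [("a", "m1"), ("a", "m2")]

    def test_k_zero_and_k_too_large(self):
        scores = self._frame([("a", "m1", 1.0, 1)])
        assert len(attribution.select_top_pairs(scores, K=0)) == 0
        with pytest.warns(UserWarning, match="truncating"):
            assert len(attribution.select_top_pairs(scores, K=5)) == 1


class TestBiNetwork:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["mgs_id", "metabolite_id", "score", "sign"])

    def test_hub_degree(self):
        net = attribution.build_binetwork(
            self._edges([("g", "m1", 1, 1), ("g", "m2", 1, 1), ("g", "m3", 1, 1)])
        )
        assert net.number_of_nodes() == 4
        assert net.degree["g"] == 3

    def test_empty_edge_list(self):
        net = attribution.build_binetwork(self._edges([]))
        assert net.number_of_nodes() == 0

    def test_duplicate_edges_keep_max_weight(self):
        net = attribution.build_binetwork(
            self._edges([("g", "m", 0.2, 1), ("g", "m", 0.7, -1), ("g", "m", 0.4, 1)])
        )
        assert net.number_of_edges() == 1
        assert net["g"]["m"]["weight"] == 0.7
        assert net["g"]["m"]["sign"] == -1

    def test_type_collision_raises(self):
        with pytest.raises(ValueError, match="both"):
            attribution.build_binetwork(
                self._edges([("x", "m", 1, 1), ("g", "x", 1, 1)])
            )


class TestCentrality:
    def _net(self, pairs):
        return attribution.build_binetwork(
            pd.DataFrame(
                [(u, v, 1.0, 1) for u, v in pairs],
                columns=["mgs_id", "metabolite_id", "score", "sign"],
            )
        )

    def test_path_graph(self):
        # path g1 - m - g2: the metabolite bridges one pair
        table = attribution.node_centrality(self._net([("g1", "m"), ("g2", "m")])).set_index(
            "node_id"
        )
        assert table.loc["m", "degree"] == 2
        assert table.loc["m", "betweenness"] == 1.0
        assert table.loc["g1", "betweenness"] == 0.0

    def test_star_hub(self):
        table = attribution.node_centrality(
            self._net([("h", f"m{i}") for i in range(4)])
        ).set_index("node_id")
        assert table.loc["h", "degree"] == 4
        assert table.loc["h", "betweenness"] == math.comb(4, 2)

    def test_single_edge_graph(self):
        table = attribution.node_centrality(self._net([("g", "m")]))
        assert (table["betweenness"] == 0).all()

    def test_matches_brute_force_on_random_small_graphs(self):
        from micromet.experiments import centrality_oracle

        assert centrality_oracle(seed=5, n_graphs=30)["all_agree"]


def test_planted_keystone_tops_degree_ranking():
    from micromet.experiments import keystone_recovery

    res = keystone_recovery(seed=42, n_seeds=10)
    assert res["top_rank_rate"] >= 0.9
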