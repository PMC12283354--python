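"""Shapley attribution of fitted tree ensembles and the MGS-metabolite bi-network.

Per-sample, per-feature Shapley values are computed with the exact
path-dependent TreeSHAP algorithm (LightGBM's native ``pred_contrib``
implementation).  Local accuracy -- base value plus the attributions of one
sample summing to that sample's prediction -- holds to machine precision and
is asserted downstream.

Attributions are aggregated to one (score, sign) per feature (mean |phi|
across samples, sign of the mean phi), pooled across metabolite models into
(MGS, metabolite, score) triples, and the K pairs with the largest scores
form a strictly bipartite network whose degree and betweenness centralities
rank candidate keystone species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class AttributionMatrix:
    """Shapley values of one fitted model: ``phi`` is n x p, plus base value."""

    metabolite_id: str
    base_value: float
    phi: np.ndarray
    feature_names: list[str]
    predictions: np.ndarray

    def local_accuracy_error(self) -> float:
        """max over samples of |base + sum(phi) - prediction|."""
        return float(np.abs(self.base_value + self.phi.sum(axis=1) - self.predictions).max())


def attribution_values(model, X, feature_names=None, metabolite_id: str = "") -> AttributionMatrix:
    """Exact tree-Shapley values of a LightGBM model on a design matrix."""
    booster = getattr(model, "booster_", model)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != booster.num_feature():
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"model expects {booster.num_feature()}"
        )
    contrib = booster.predict(X, pred_contrib=True)
    phi, base = contrib[:, :-1], contrib[:, -1]
    pred = booster.predict(X)
    if feature_names is None:
        feature_names = booster.feature_name()
    return AttributionMatrix(metabolite_id, float(base[0]), phi, list(feature_names), pred)


def aggregate_attribution(attr: AttributionMatrix) -> pd.DataFrame:
    """One (score, sign) per feature: score = mean |phi|, sign = sign(mean phi)."""
    if attr.phi.size == 0:
        raise ValueError("empty attribution matrix")
    score = np.abs(attr.phi).mean(axis=0)
    sign = np.sign(attr.phi.mean(axis=0))
    return pd.DataFrame(
        {"feature": attr.feature_names, "score": score, "sign": sign.astype(int)}
    ).set_index("feature")


def signed_importance(attr: AttributionMatrix, X) -> np.ndarray:
    """Directional importance: mean |phi| signed by the phi-feature correlation.

    Attributions average to ~0 across samples (the base value absorbs the
    mean), so the sign of the *association* between phi and the feature
    value carries the direction -- this is the quantity comparable to a
    linear model's coefficients.
    """
    X = np.asarray(X, dtype=float)
    score = np.abs(attr.phi).mean(axis=0)
    signs = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        sx = X[:, j].std()
        sp = attr.phi[:, j].std()
        if sx == 0 or sp == 0:
            signs[j] = 0.0
        else:
            signs[j] = np.sign(np.corrcoef(attr.phi[:, j], X[:, j])[0, 1])
    return score * signs


def pool_mgs_scores(
    attributions: dict[str, AttributionMatrix], mgs_features: list[str]
) -> pd.DataFrame:
    """Pool per-metabolite aggregates into (mgs, metabolite, score, sign) triples.

    Only MGS features enter the network even when the models were fit on the
    combined feature set.
    """
    rows = []
    mgs_set = set(mgs_features)
    for met, attr in attributions.items():
        agg = aggregate_attribution(attr)
        for feat, row in agg.iterrows():
            if feat in mgs_set:
                rows.append((feat, met, float(row["score"]), int(row["sign"])))
    return pd.DataFrame(rows, columns=["mgs_id", "metabolite_id", "score", "sign"])


def select_top_pairs(scores: pd.DataFrame, K: int = 300) -> pd.DataFrame:
    """K pairs with the largest scores; ties broken by (mgs_id, metabolite_id)."""
    if K > len(scores):
        warnings.warn(f"K = {K} exceeds {len(scores)} available pairs; truncating", stacklevel=2)
        K = len(scores)
    ordered = scores.sort_values(
        ["score", "mgs_id", "metabolite_id"], ascending=[False, True, True], kind="mergesort"
    )
    return ordered.head(K).reset_index(drop=True)


def build_binetwork(edges: pd.DataFrame) -> nx.Graph:
    """Bipartite MGS-metabolite graph from an edge list.

    Duplicate edges collapse keeping the maximum weight.  A node id used on
    both sides raises a type-collision error.
    """
    mgs_ids = set(edges["mgs_id"])
    met_ids = set(edges["metabolite_id"])
    clash = mgs_ids & met_ids
    if clash:
        raise ValueError(f"ids used as both MGS and metabolite: {sorted(clash)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(mgs_ids, kind="MGS", bipartite=0)
    g.add_nodes_from(met_ids, kind="metabolite", bipartite=1)
    for _, row in edges.iterrows():
        u, v = row["mgs_id"], row["metabolite_id"]
        w = float(row["score"])
        if g.has_edge(u, v):
            if w > g[u][v]["weight"]:
                g[u][v]["weight"] = w
                g[u][v]["sign"] = int(row.get("sign", 0))
        else:
            g.add_edge(u, v, weight=w, sign=int(row.get("sign", 0)))
    return g


def node_centrality(net: nx.Graph) -> pd.DataFrame:
    """Degree and shortest-path betweenness per node.

    ``betweenness`` counts node pairs (unnormalized, computed within
    connected components); ``betweenness_norm`` divides by
    (N-1)(N-2)/2 of the whole graph.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(net.degree())
    bet = nx.betweenness_centrality(net, normalized=False)
    n = net.number_of_nodes()
    denom = (n - 1) * (n - 2) / 2
    table = pd.DataFrame(
        {
            "node_id": list(net.nodes),
            "kind": [net.nodes[v].get("kind", "") for v in net.nodes],
            "degree": [degree[v] for v in net.nodes],
            "betweenness": [bet[v] for v in net.nodes],
            "betweenness_norm": [bet[v] / denom if denom > 0 else 0.0 for v in net.nodes],
        }
    )
    return table.sort_values(
        ["degree", "betweenness", "node_id"], ascending=[False, False, True]
    ).reset_index(drop=True)


def layout_positions(net: nx.Graph, seed: int = 0) -> dict:
    """Force-directed node coordinates for export (never part of analysis)."""
    return nx.spring_layout(net, seed=seed)
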