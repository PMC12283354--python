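"""Self-contained simulation experiments exercising the pipeline end to end.

Each function generates its own synthetic inputs (via :mod:`micromet.synthgen`
or plain draws), runs one method, and returns the measured quantities as a
plain dict.  The analysis drivers, the test suite and the acceptance script
all call these, so the numbers they report are produced by the same code
paths.  Every function takes a single integer ``seed`` controlling all of
its randomness.

Problem sizes are chosen so the full battery runs on one CPU in well under
an hour; docs/methods.md records the sizes and the reasoning.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution, classify, ev, mediation, pipeline, signatures, synthgen
from .dataio import MetaboliteMatrix, preprocess_metabolites


# ---------------------------------------------------------------------------
# explained-variance inference
# ---------------------------------------------------------------------------

def ev_null_calibration(
    seed: int = 0,
    n: int = 200,
    p: int = 20,
    B: int = 100,
    n_replicates: int = 200,
    alpha: float = 0.05,
    n_perm: int = 10,
) -> dict:
    """Type-I error of the EV Wald test when the target is independent of X.

    Draws ``n_replicates`` null datasets (y and X independent Gaussians),
    runs the full bootstrap + permutation EV inference on each, and reports
    the fraction of two-sided P values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    spec = ev.GBDTSpec.fast()
    rejections = 0
    points = []
    ci_misses = 0
    for _ in range(n_replicates):
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        res = ev.ev_bootstrap(
            X, y, B=B, k=5, spec=spec, seed=int(rng.integers(2**31)), n_perm=n_perm
        )
        points.append(res.r2)
        rejections += res.p < alpha
        ci_misses += not (res.ci_low <= res.r2 <= res.ci_high)
    return {
        "rejection_rate": rejections / n_replicates,
        "ci_miss_rate": ci_misses / n_replicates,
        "mean_point_r2": float(np.mean(points)),
        "n_replicates": n_replicates,
    }


def ev_recovery(
    seed: int = 0,
    target: float = 0.4,
    n: int = 1000,
    p_m: int = 50,
    n_seeds: int = 10,
    n_repeats: int = 3,
) -> dict:
    """Recovery of a planted microbiome signal fraction by the EV estimator.

    Per seed: a fresh cohort, one metabolite with the planted fraction,
    point EV from repeated 5-fold CV with the full hyperparameter search.
    Reports the median estimate across seeds.
    """
    rng = np.random.default_rng(seed)
    spec = ev.GBDTSpec(num_boost_round=120)
    estimates = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        bundle = synthgen.gen_feature_bundle(n, 6, p_m, 8, seed=s)
        metab, _ = synthgen.gen_metabolite_matrix(
            bundle, {"m": synthgen.MetaboliteSignal(microbiome=target)}, seed=s + 1
        )
        y = metab["m"].to_numpy()
        X = ev.assemble_design(bundle)["microbiome"]
        pred = ev.oof_predict(X, y, k=5, spec=spec, seed=s + 2, n_repeats=n_repeats)
        estimates.append(ev.explained_variance(y, pred))
    return {
        "median_r2": float(np.median(estimates)),
        "estimates": estimates,
        "target": target,
        "n": n,
    }


def relative_power_ordering(
    seed: int = 0,
    n_seeds: int = 20,
    n: int = 400,
    fractions: tuple[float, float, float] = (0.4, 0.2, 0.1),
    n_metabolites: int = 20,
) -> dict:
    """How often the relative-power shares recover a planted 4:2:1 ordering.

    Every metabolite carries the same clinical/microbiome/diet signal
    fractions; a seed counts as correct when the recovered shares are
    strictly ordered clinical > microbiome > diet.
    """
    rng = np.random.default_rng(seed)
    spec = ev.GBDTSpec.fast()
    correct = 0
    shares_all = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        bundle = synthgen.gen_feature_bundle(n, 8, 30, 10, seed=s)
        plan = {
            f"met_{i:02d}": synthgen.MetaboliteSignal(
                clinical=fractions[0], microbiome=fractions[1], diet=fractions[2],
                n_active=3,
            )
            for i in range(n_metabolites)
        }
        metab, _ = synthgen.gen_metabolite_matrix(bundle, plan, seed=s + 1)
        std = (metab - metab.mean()) / metab.std(ddof=1)
        mm = MetaboliteMatrix(std, state="preprocessed")
        res = ev.relative_power(bundle, mm, k=5, spec=spec, seed=s + 2)
        sh = res.shares
        shares_all.append(sh)
        if sh["clinical"] > sh["microbiome"] > sh["diet"]:
            correct += 1
    mean_shares = {g: float(np.mean([s[g] for s in shares_all])) for g in synthgen.GROUPS}
    return {
        "ordering_rate": correct / n_seeds,
        "mean_shares": mean_shares,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# attribution and network
# ---------------------------------------------------------------------------

def shap_local_accuracy(seed: int = 0, n: int = 200, n_metabolites: int = 8) -> dict:
    """Max |base + sum(phi) - prediction| across freshly fitted tree models."""
    bundle = synthgen.gen_feature_bundle(n, 5, 25, 6, seed=seed)
    plan = {
        f"met_{i}": synthgen.MetaboliteSignal(microbiome=0.3, n_active=3, linear=(i % 2 == 0))
        for i in range(n_metabolites)
    }
    metab, _ = synthgen.gen_metabolite_matrix(bundle, plan, seed=seed + 1)
    X = ev.assemble_design(bundle)["microbiome"]
    worst = 0.0
    for i, met in enumerate(metab.columns):
        model = ev.fit_gbdt(X, metab[met].to_numpy(), spec=ev.GBDTSpec(n_search=2), seed=seed + i)
        am = attribution.attribution_values(model, X, metabolite_id=met)
        worst = max(worst, am.local_accuracy_error())
    return {"max_local_accuracy_error": worst, "n_models": n_metabolites}


def _brute_force_betweenness(nodes, edges) -> dict:
    """Independent betweenness oracle: enumerate all shortest paths per pair."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        # breadth-first layering, then depth-first enumeration of paths
        if s == t:
            return []
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def walk(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    walk(path + [w])

        walk([s])
        return paths

    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    return bet


def centrality_oracle(seed: int = 0, n_graphs: int = 100, max_nodes: int = 7) -> dict:
    """Agreement of degree/betweenness with brute-force path enumeration on
    random connected graphs with at most ``max_nodes`` nodes."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        nn = int(rng.integers(3, max_nodes + 1))
        # random bipartite-ish labels so node_centrality's typed table applies
        n_mgs = int(rng.integers(1, nn))
        mgs = [f"g{i}" for i in range(n_mgs)]
        mets = [f"m{i}" for i in range(nn - n_mgs)]
        nodes = mgs + mets
        possible = [(u, v) for u in mgs for v in mets]
        if not possible:
            continue
        k = int(rng.integers(1, len(possible) + 1))
        chosen = [possible[i] for i in rng.choice(len(possible), size=k, replace=False)]
        edges = pd.DataFrame(
            [(u, v, 1.0, 1) for u, v in chosen],
            columns=["mgs_id", "metabolite_id", "score", "sign"],
        )
        net = attribution.build_binetwork(edges)
        # restrict to nodes with at least one edge, as the network does
        used = set(itertools.chain.from_iterable(chosen))
        table = attribution.node_centrality(net).set_index("node_id")
        oracle_bet = _brute_force_betweenness(sorted(used), chosen)
        oracle_deg = {v: sum(1 for e in chosen if v in e) for v in used}
        ok = all(
            table.loc[v, "degree"] == oracle_deg[v]
            and abs(table.loc[v, "betweenness"] - oracle_bet[v]) < 1e-9
            for v in used
        )
        agree += ok
    return {"n_graphs": n_graphs, "n_agree": agree, "all_agree": agree == n_graphs}


def keystone_recovery(seed: int = 0, n_seeds: int = 20, n: int = 250) -> dict:
    """Does the planted hub MGS reach the top degree rank in the bi-network?

    One MGS drives ten metabolites, the others at most two; counts the
    seeds in which that MGS attains the (possibly tied) maximum degree.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        bundle = synthgen.gen_feature_bundle(n, 5, 30, 6, seed=s)
        plan = {}
        for i in range(10):
            plan[f"hubmet_{i}"] = synthgen.MetaboliteSignal(
                microbiome=0.4, active={"microbiome": [0, 1 + (i % 5)]}
            )
        for i in range(6):
            plan[f"othmet_{i}"] = synthgen.MetaboliteSignal(
                microbiome=0.4, active={"microbiome": [6 + 2 * i, 7 + 2 * i]}
            )
        metab, _ = synthgen.gen_metabolite_matrix(bundle, plan, seed=s + 1)
        X = ev.assemble_design(bundle)["microbiome"]
        mgs_names = list(bundle.microbiome.columns)
        attrs = {}
        for j, met in enumerate(metab.columns):
            model = ev.fit_gbdt(X, metab[met].to_numpy(), spec=ev.GBDTSpec.fast(), seed=s + 2 + j)
            attrs[met] = attribution.attribution_values(
                model, X, feature_names=mgs_names, metabolite_id=met
            )
        scores = attribution.pool_mgs_scores(attrs, mgs_names)
        edges = attribution.select_top_pairs(scores, K=40)
        cent = attribution.node_centrality(attribution.build_binetwork(edges))
        mgs_rows = cent[cent["kind"] == "MGS"]
        top_degree = mgs_rows["degree"].max()
        hub_rows = mgs_rows[mgs_rows["node_id"] == "mgs_0000"]
        if len(hub_rows) and hub_rows["degree"].iloc[0] == top_degree:
            hits += 1
    return {"top_rank_rate": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

def mediation_recovery(
    seed: int = 0,
    a: float = 0.5,
    b: float = 0.5,
    c_prime: float = 0.25,
    n: int = 5000,
    B: int = 1000,
) -> dict:
    """Proportion-mediated estimate on one large planted triplet."""
    table, meta, truth = synthgen.gen_mediation_triplet(n, a, b, c_prime, seed=seed)
    res = mediation.fit_mediation(
        table["mgs1"],
        table["mediator"],
        table["mgs2"],
        meta.table[["age", "bmi", "sex"]].to_numpy(dtype=float),
        B=B,
        seed=seed + 1,
    )
    return {
        "prop_mediated": res.prop_mediated,
        "analytic": truth.mediation["triplet"]["proportion"],
        "acme": res.acme,
        "p": res.p,
    }


def mediation_coverage(
    seed: int = 0,
    n_sims: int = 200,
    n: int = 500,
    B: int = 200,
    a: float = 0.5,
    b: float = 0.5,
    c_prime: float = 0.25,
) -> dict:
    """Coverage of the 95% bootstrap ACME CI over repeated planted triplets.

    Fits on the structural scale (centred, unstandardized) so the planted
    ACME a*b is the estimand.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_sims):
        s = int(rng.integers(2**31))
        table, meta, _ = synthgen.gen_mediation_triplet(n, a, b, c_prime, seed=s)
        res = mediation.fit_mediation(
            table["mgs1"],
            table["mediator"],
            table["mgs2"],
            meta.table[["age", "bmi", "sex"]].to_numpy(dtype=float),
            B=B,
            seed=s + 1,
            standardize=False,
        )
        if res.ci_acme[0] <= a * b <= res.ci_acme[1]:
            covered += 1
    return {"coverage": covered / n_sims, "n_sims": n_sims, "acme_true": a * b}


# ---------------------------------------------------------------------------
# exact-statistic oracles
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_check(max_m: int = 5, max_n: int = 5) -> dict:
    """Compare the exact rank-sum P against full enumeration of group splits
    for every tie-free pair of group sizes up to (max_m, max_n)."""
    worst = 0.0
    n_checked = 0
    rng = np.random.default_rng(12345)
    for m in range(2, max_m + 1):
        for nn in range(2, max_n + 1):
            vals = rng.normal(size=m + nn)  # continuous => tie-free
            a, bvals = vals[:m], vals[m:]
            _, p, _ = signatures.wilcoxon_rank_sum(a, bvals)
            # enumeration oracle: distribution of the rank-sum over all
            # equally likely assignments of ranks to group A
            ranks = np.argsort(np.argsort(vals)) + 1
            w_obs = ranks[:m].sum()
            mean_w = m * (m + nn + 1) / 2
            stats_all = [
                sum(c) for c in itertools.combinations(range(1, m + nn + 1), m)
            ]
            stats_all = np.array(stats_all)
            p_enum = np.mean(np.abs(stats_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
            worst = max(worst, abs(p - p_enum))
            n_checked += 1
    return {"max_abs_diff": worst, "n_checked": n_checked}


def exact_statistic_oracles() -> dict:
    """Closed-form checks: chi-squared, AUC, 2x2 logistic OR, rank-sum P."""
    chi2, dof, _ = signatures.proportion_test([[30, 70], [10, 90]])
    auc = classify.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    # 2x2 table (case-exposed 10, case-unexposed 20, control-exposed 30,
    # control-unexposed 40): cross-product OR = (10*40)/(20*30)
    y = np.repeat([1, 1, 0, 0], [10, 20, 30, 40])
    x = np.repeat([1, 0, 1, 0], [10, 20, 30, 40])
    or_res = signatures.adjusted_odds_ratio(y, x)
    _, p_ranksum, _ = signatures.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    wil = wilcoxon_enumeration_check()
    return {
        "chi2_example": chi2,
        "chi2_df": dof,
        "auc_example": auc,
        "or_2x2": or_res.or_value,
        "wilcoxon_small_p": p_ranksum,
        "wilcoxon_enum_max_diff": wil["max_abs_diff"],
    }


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _planted_classification(n, p, shift, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.integers(0, 2, n)
    X[y == 1, 0] += shift
    X[y == 1, 1] += shift
    return X, y


def classifier_sanity(
    seed: int = 0,
    n: int = 300,
    p: int = 20,
    shift: float = 2.0,
    n_null_seeds: int = 20,
    n_trees: int = 200,
) -> dict:
    """Planted-signal CV AUC and the mean null (permuted-label) CV AUC."""
    X, y = _planted_classification(n, p, shift, seed)
    cv, _ = classify.rf_cv_classifier(X, y, n_trees=n_trees, folds=5, repeats=2, seed=seed)
    rng = np.random.default_rng(seed + 1)
    null_aucs = []
    for _ in range(n_null_seeds):
        s = int(rng.integers(2**31))
        Xn = rng.normal(size=(n, p))
        yn = rng.integers(0, 2, n)
        cvn, _ = classify.rf_cv_classifier(Xn, yn, n_trees=100, folds=5, repeats=1, seed=s)
        null_aucs.append(cvn.mean_metric)
    return {
        "planted_auc": cv.mean_metric,
        "null_auc_mean": float(np.mean(null_aucs)),
        "null_aucs": null_aucs,
    }


# ---------------------------------------------------------------------------
# demo pipeline determinism
# ---------------------------------------------------------------------------

REDUCED_DEMO = {
    "simulate": {"n": 150, "p_microbiome": 30, "n_metabolites": 16},
    "ev": {"n_boot": 30, "n_perm": 5},
    "network": {"top_k": 60},
    "mediate": {"n_boot": 200},
    "classify": {"n_trees": 100, "folds": 5, "repeats": 1},
}


def demo_determinism(seed: int = 0, workdir: str | None = None, reduced: bool = False) -> dict:
    """Run the demo configuration twice into fresh directories and compare
    the SHA-256 digests of every stage output.

    ``reduced=True`` uses a smaller cohort/bootstrap configuration; the
    determinism contract under test is identical.
    """
    import time as _time

    cfg = {"seed": seed, **(REDUCED_DEMO if reduced else {})}
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(ctx.name if ctx else workdir)
    t0 = _time.time()
    m1 = pipeline.run_pipeline(cfg, base / "run1")
    elapsed_first = _time.time() - t0
    m2 = pipeline.run_pipeline(cfg, base / "run2")
    identical = True
    mismatches = []
    for stage in m1["stages"]:
        f1 = {k: v["sha256"] for k, v in m1["stages"][stage]["files"].items()}
        f2 = {k: v["sha256"] for k, v in m2["stages"][stage]["files"].items()}
        if f1 != f2:
            identical = False
            mismatches.append(stage)
    max_shap_err = m1["stages"]["attribute"].get("max_local_accuracy_error", float("nan"))
    if ctx:
        ctx.cleanup()
    return {
        "identical_digests": identical,
        "mismatched_stages": mismatches,
        "elapsed_first_run_s": elapsed_first,
        "demo_max_local_accuracy_error": max_shap_err,
    }


# ---------------------------------------------------------------------------
# preprocessing toy example
# ---------------------------------------------------------------------------

def preprocessing_toy() -> dict:
    """Hand-computed chain: (1, 10, 100, missing) -> log10 -> (0,1,2) ->
    min-impute -> (0,1,2,0) -> standardize (sample SD)."""
    raw = MetaboliteMatrix(
        pd.DataFrame({"m": [1.0, 10.0, 100.0, np.nan]}, index=list("abcd")), state="raw"
    )
    prep, _ = preprocess_metabolites(raw, min_measurements=3)
    vals = np.array([0.0, 1.0, 2.0, 0.0])
    expected = (vals - vals.mean()) / vals.std(ddof=1)
    err = float(np.abs(prep.values["m"].to_numpy() - expected).max())
    return {"max_abs_error": err, "expected": expected.tolist()}
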