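"""End-to-end pipeline: simulate -> preprocess -> ev -> attribute -> network ->
mediate -> signatures -> classify -> report.

A run is driven by one structured configuration (YAML/dict, validated
against a small schema), writes every stage output as plain TSV/JSON under
the output directory, and records a manifest with per-stage seeds, file
SHA-256 digests and timings.  Reruns with an unchanged configuration skip
stages whose recorded signature and output digests still match.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import attribution, classify, dataio, ev, mediation, signatures, synthgen

STAGES = (
    "simulate",
    "preprocess",
    "ev",
    "attribute",
    "network",
    "mediate",
    "signatures",
    "classify",
    "report",
)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n": 300,
        "p_clinical": 8,
        "p_microbiome": 60,
        "p_diet": 15,
        "zero_inflation": 0.3,
        "n_metabolites": 40,
        "keystone_mgs": 0,  # index of the MGS planted to drive many metabolites
    },
    "ev": {"n_boot": 100, "folds": 5, "n_perm": 5, "fast": True},
    "network": {"top_k": 300},
    "mediate": {"n_boot": 1000},
    "signatures": {"contrasts": ["IFG", "IGT", "CGI", "T2D"]},
    "classify": {"n_trees": 300, "folds": 5, "repeats": 2},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge over defaults and check schema bounds; raise naming the key."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in merged:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(val, dict):
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    raise ConfigError(f"unknown configuration key {key}.{k2}")
                merged[key][k2] = v2
        else:
            merged[key] = val
    if merged["ev"]["folds"] < 2:
        raise ConfigError("ev.folds must be >= 2")
    if merged["classify"]["folds"] < 2:
        raise ConfigError("classify.folds must be >= 2")
    if merged["simulate"]["n"] < 10:
        raise ConfigError("simulate.n must be >= 10")
    if merged["ev"]["n_boot"] < 1:
        raise ConfigError("ev.n_boot must be >= 1")
    return merged


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _signal_plan(sim_cfg: dict) -> dict[str, synthgen.MetaboliteSignal]:
    """Deterministic planted-signal plan for the demo cohort.

    One keystone MGS drives ten microbiome metabolites; other metabolites
    are clinical-, diet-, mixed- or noise-driven, so every downstream stage
    has structure to find.
    """
    q = sim_cfg["n_metabolites"]
    key = sim_cfg["keystone_mgs"]
    plan = {}
    rng = np.random.default_rng(1234)
    p_m = sim_cfg["p_microbiome"]
    for i in range(q):
        name = f"met_{i:03d}"
        if i < 10:  # microbiome-driven, keystone among the actives
            others = 1 + (np.arange(2) + 2 * i) % (p_m - 1)
            plan[name] = synthgen.MetaboliteSignal(
                microbiome=0.35,
                active={"microbiome": [key, *others.tolist()]},
            )
        elif i < 14:  # microbiome-driven without the keystone
            others = 1 + rng.choice(p_m - 1, 3, replace=False)
            plan[name] = synthgen.MetaboliteSignal(
                microbiome=0.3, active={"microbiome": others.tolist()}
            )
        elif i < 22:
            plan[name] = synthgen.MetaboliteSignal(clinical=0.3, n_active=3)
        elif i < 28:
            plan[name] = synthgen.MetaboliteSignal(diet=0.25, n_active=3)
        elif i < 34:
            plan[name] = synthgen.MetaboliteSignal(clinical=0.2, microbiome=0.2, n_active=3)
        else:
            plan[name] = synthgen.MetaboliteSignal()
    return plan


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old_manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    manifest = {
        "version": __version__,
        "config": cfg,
        "stages": {},
    }

    def stage_done(name: str, files: dict[str, Path], extra: dict | None = None):
        entry = {
            "seed": _stage_seed(cfg["seed"], name),
            "signature": _signature(cfg, name),
            "files": {k: {"path": str(p.relative_to(out)), "sha256": _digest(p)} for k, p in files.items()},
            "elapsed_s": round(time.time() - t0, 3),
        }
        if extra:
            entry.update(extra)
        manifest["stages"][name] = entry
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def cached(name: str) -> bool:
        entry = old_manifest.get("stages", {}).get(name)
        if not entry or entry.get("signature") != _signature(cfg, name):
            return False
        for rec in entry["files"].values():
            p = out / rec["path"]
            if not p.exists() or _digest(p) != rec["sha256"]:
                return False
        manifest["stages"][name] = entry
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return True

    # -- simulate ----------------------------------------------------------
    t0 = time.time()
    sim = cfg["simulate"]
    seed = _stage_seed(cfg["seed"], "simulate")
    bundle = synthgen.gen_feature_bundle(
        sim["n"], sim["p_clinical"], sim["p_microbiome"], sim["p_diet"],
        zero_inflation=sim["zero_inflation"], seed=seed,
    )
    plan = _signal_plan(sim)
    raw_std, truth = synthgen.gen_metabolite_matrix(bundle, plan, seed=seed + 1)
    raw = synthgen.to_raw_abundance_scale(raw_std, seed=seed + 2)
    shifts = {m: {"T2D": 0.8, "CGI": 0.5} for m in list(raw.columns)[:6]}
    meta, raw, truth_lab = synthgen.gen_cohort_labels(
        sim["n"], raw, planted_shifts=shifts, seed=seed + 3
    )
    truth.differential = truth_lab.differential
    if not cached("simulate"):
        files = synthgen.write_cohort(out / "cohort", bundle, raw, meta, truth)
        stage_done("simulate", files)

    # -- preprocess --------------------------------------------------------
    t0 = time.time()
    raw_mm = dataio.MetaboliteMatrix(raw, state="raw")
    prep, report = dataio.preprocess_metabolites(raw_mm)
    if not cached("preprocess"):
        p = out / "metabolites_preprocessed.tsv"
        prep.values.to_csv(p, sep="\t", index_label="sample_id", na_rep="NA")
        stage_done("preprocess", {"metabolites": p},
                   {"n_raw": report.n_raw, "n_kept": report.n_kept})

    # -- ev ----------------------------------------------------------------
    t0 = time.time()
    evc = cfg["ev"]
    spec = ev.GBDTSpec.fast() if evc["fast"] else ev.GBDTSpec()
    ev_path = out / "results_ev.tsv"
    if not cached("ev"):
        table = ev.ev_table(
            bundle, prep, B=evc["n_boot"], k=evc["folds"], spec=spec,
            seed=_stage_seed(cfg["seed"], "ev"), n_perm=evc["n_perm"],
        )
        table.to_csv(ev_path, sep="\t", index=False, float_format="%.10g")
        stage_done("ev", {"ev": ev_path})
    ev_tab = pd.read_csv(ev_path, sep="\t")

    # -- attribute ---------------------------------------------------------
    t0 = time.time()
    mats = ev.assemble_design(bundle)
    seed_attr = _stage_seed(cfg["seed"], "attribute")
    attrs = {}
    mgs_names = list(bundle.microbiome.columns)
    for i, met in enumerate(prep.metabolite_ids):
        model = ev.fit_gbdt(
            mats["microbiome"], prep.values[met].to_numpy(), spec=spec, seed=seed_attr + i
        )
        attrs[met] = attribution.attribution_values(
            model, mats["microbiome"], feature_names=mgs_names, metabolite_id=met
        )
    scores = attribution.pool_mgs_scores(attrs, mgs_names)
    if not cached("attribute"):
        p = out / "attribution_scores.tsv"
        scores.to_csv(p, sep="\t", index=False, float_format="%.10g")
        local_err = max(a.local_accuracy_error() for a in attrs.values())
        stage_done("attribute", {"scores": p}, {"max_local_accuracy_error": local_err})

    # -- network -----------------------------------------------------------
    t0 = time.time()
    edges = attribution.select_top_pairs(scores, K=min(cfg["network"]["top_k"], len(scores)))
    net = attribution.build_binetwork(edges)
    cent = attribution.node_centrality(net)
    if not cached("network"):
        pe = out / "network_edges.tsv"
        pc = out / "network_centrality.tsv"
        edges.to_csv(pe, sep="\t", index=False, float_format="%.10g")
        cent.to_csv(pc, sep="\t", index=False, float_format="%.10g")
        stage_done("network", {"edges": pe, "centrality": pc})

    # -- mediate -----------------------------------------------------------
    t0 = time.time()
    micro_log = dataio.transform_microbiome(bundle.microbiome)
    hub = cent.loc[cent["kind"] == "MGS", "node_id"].iloc[0]
    other = cent.loc[(cent["kind"] == "MGS") & (cent["node_id"] != hub), "node_id"].iloc[0]
    med_metab = edges.loc[edges["mgs_id"] == hub, "metabolite_id"].iloc[0]
    covars = meta.table[["age", "bmi", "sex"]].to_numpy(dtype=float)
    fwd, rev = mediation.bidirectional_mediation(
        micro_log[hub].to_numpy(),
        micro_log[other].to_numpy(),
        prep.values[med_metab].to_numpy(),
        covars,
        B=cfg["mediate"]["n_boot"],
        seed=_stage_seed(cfg["seed"], "mediate"),
        names=(hub, med_metab, other),
    )
    if not cached("mediate"):
        p = out / "mediation.tsv"
        mediation.mediation_table([fwd, rev]).to_csv(p, sep="\t", index=False, float_format="%.10g")
        stage_done("mediate", {"mediation": p})

    # -- signatures --------------------------------------------------------
    t0 = time.time()
    sig_frames = []
    for grp in cfg["signatures"]["contrasts"]:
        if (meta.table["group"] == grp).sum() >= 3:
            sig_frames.append(
                signatures.differential_metabolites(prep.values, meta, (grp, "NGT"))
            )
    sig = pd.concat(sig_frames, ignore_index=True)
    if not cached("signatures"):
        p = out / "signatures.tsv"
        sig.to_csv(p, sep="\t", index=False, float_format="%.10g")
        stage_done("signatures", {"signatures": p})

    # -- classify ----------------------------------------------------------
    t0 = time.time()
    cls = cfg["classify"]
    is_case = meta.table["group"].isin(["CGI", "T2D"]).to_numpy()
    is_ngt = (meta.table["group"] == "NGT").to_numpy()
    keep = is_case | is_ngt
    cv, _ = classify.rf_cv_classifier(
        prep.values.to_numpy()[keep],
        is_case[keep].astype(int),
        n_trees=cls["n_trees"],
        folds=cls["folds"],
        repeats=cls["repeats"],
        seed=_stage_seed(cfg["seed"], "classify"),
    )
    if not cached("classify"):
        p = out / "classifier_cv.tsv"
        pd.DataFrame({"fold": np.arange(len(cv.fold_metrics)), "auc": cv.fold_metrics}).to_csv(
            p, sep="\t", index=False, float_format="%.10g"
        )
        pj = out / "classifier_model.json"
        pj.write_text(json.dumps({"mean_auc": cv.mean_metric, **cv.model_descriptor}, indent=1))
        stage_done("classify", {"cv": p, "model": pj})

    # -- report ------------------------------------------------------------
    t0 = time.time()
    if not cached("report"):
        p = out / "report.txt"
        p.write_text(render_report(out))
        stage_done("report", {"report": p})
    return manifest


def _signature(cfg: dict, stage: str) -> str:
    """Hash of the configuration subset a stage depends on."""
    idx = STAGES.index(stage)
    relevant = {"seed": cfg["seed"]}
    for s in STAGES[: idx + 1]:
        if s in cfg:
            relevant[s] = cfg[s]
    return hashlib.sha256(json.dumps(relevant, sort_keys=True).encode()).hexdigest()


def render_report(results_dir: str | Path) -> str:
    """Human-readable summary of a completed run; lists missing stages."""
    out = Path(results_dir)
    lines = ["micromet run summary", "=" * 40]
    missing = []

    ev_path = out / "results_ev.tsv"
    if ev_path.exists():
        tab = pd.read_csv(ev_path, sep="\t")
        lines.append("\nExplained variance per feature group (out-of-sample R2):")
        for g, sub in tab.groupby("group"):
            n_sig = int((sub["q"] < signatures.Q_GATE).sum())
            lines.append(
                f"  {g:<12} median EV {sub['r2'].median():+.3f}  max {sub['r2'].max():+.3f}"
                f"  significant (q<0.1): {n_sig}/{len(sub)}"
            )
    else:
        missing.append("ev")

    cent_path = out / "network_centrality.tsv"
    if cent_path.exists():
        cent = pd.read_csv(cent_path, sep="\t")
        hubs = cent[cent["kind"] == "MGS"].head(5)
        lines.append("\nTop network hubs (MGS, by degree then betweenness):")
        for _, r in hubs.iterrows():
            lines.append(
                f"  {r['node_id']:<12} degree {int(r['degree'])}  betweenness {r['betweenness']:.1f}"
            )
    else:
        missing.append("network")

    med_path = out / "mediation.tsv"
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t")
        lines.append("\nBidirectional mediation:")
        for _, r in med.iterrows():
            prop = f"{100 * r['prop_mediated']:.1f}%" if r["prop_defined"] else "undefined"
            lines.append(
                f"  {r['exposure']} -> {r['mediator']} -> {r['outcome']}: "
                f"proportion mediated {prop} (P = {r['p']:.3g})"
            )
    else:
        missing.append("mediate")

    sig_path = out / "signatures.tsv"
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
        n_sig = int(sig["significant"].sum())
        lines.append(f"\nDifferential metabolites: {n_sig} significant calls (q < 0.1) "
                     f"over {sig['comparison'].nunique()} contrasts")
    else:
        missing.append("signatures")

    cls_path = out / "classifier_model.json"
    if cls_path.exists():
        info = json.loads(cls_path.read_text())
        lines.append(f"\nCGI/T2D-vs-NGT classifier: mean CV AUC {info['mean_auc']:.3f}")
    else:
        missing.append("classify")

    if missing:
        lines.append("\nMissing stages: " + ", ".join(missing))
    return "\n".join(lines) + "\n"
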