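#!/usr/bin/env python
"""Bidirectional mediation between the two top hub MGSs through a shared
metabolite, adjusted for age, BMI and sex (B=1000 pairs bootstrap).

Also validates the estimator on planted triplets: proportion recovery at
n=5000 and ACME CI coverage over repeated simulations.  Writes
results/mediation.tsv and results/mediation_validation.json.
"""

import json
from pathlib import Path

import pandas as pd

from micromet import dataio, experiments, mediation
from micromet.cli import _read_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    d = RESULTS / "cohort_discovery"
    bundle = _read_bundle(d)
    prep = dataio.read_table(d / "metabolites_preprocessed.tsv", "features")
    meta = dataio.read_table(d / "metadata.tsv", "metadata")
    cent = pd.read_csv(RESULTS / "network_centrality.tsv", sep="\t")
    edges = pd.read_csv(RESULTS / "network_edges.tsv", sep="\t")
    hubs = cent.loc[cent["kind"] == "MGS", "node_id"].head(2).tolist()
    shared = edges.loc[edges["mgs_id"] == hubs[0], "metabolite_id"].iloc[0]
    micro_log = dataio.transform_microbiome(bundle.microbiome)
    fwd, rev = mediation.bidirectional_mediation(
        micro_log[hubs[0]].to_numpy(),
        micro_log[hubs[1]].to_numpy(),
        prep[shared].to_numpy(),
        meta[["age", "bmi", "sex"]].to_numpy(dtype=float),
        B=1000,
        seed=55,
        names=(hubs[0], shared, hubs[1]),
    )
    mediation.mediation_table([fwd, rev]).to_csv(
        RESULTS / "mediation.tsv", sep="\t", index=False, float_format="%.10g"
    )
    for r in (fwd, rev):
        prop = f"{100 * r.prop_mediated:.1f}%" if r.prop_defined else "undefined"
        print(f"{r.exposure_id} -> {r.mediator_id} -> {r.outcome_id}: "
              f"proportion mediated {prop} (P = {r.p:.3g})")

    rec = experiments.mediation_recovery(seed=56, n=5000, B=1000)
    cov = experiments.mediation_coverage(seed=57, n_sims=100)
    (RESULTS / "mediation_validation.json").write_text(
        json.dumps({"planted_recovery": rec, "acme_ci_coverage": cov}, indent=1)
    )
    print(f"planted triplet: estimated proportion {rec['prop_mediated']:.3f} "
          f"(analytic {rec['analytic']:.2f}); ACME CI coverage {cov['coverage']:.2f}")


if __name__ == "__main__":
    main()
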