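#!/usr/bin/env python
"""Metabolite signatures of impaired glucose control.

Per cohort and subgroup (IFG/IGT/CGI/T2D vs NGT): Wilcoxon rank-sum tests
with Storey q-values; metabolites significant with the same direction in
both cohorts are the consistent signatures.  For those, age/sex-adjusted
logistic odds ratios (CGI/T2D vs NGT), overlap summaries against the
planted truth-free sets, a chi-squared proportion test, and Ward
clustering of signed response codes.  Writes results/signatures_*.tsv and
results/signature_clusters.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from micromet import dataio, signatures, synthgen

RESULTS = Path(__file__).resolve().parent.parent / "results"
CONTRASTS = ["IFG", "IGT", "CGI", "T2D"]


def call_cohort(cohort: str) -> pd.DataFrame:
    d = RESULTS / cohort
    prep = dataio.read_table(d / "metabolites_preprocessed.tsv", "features")
    meta = synthgen.SampleMetadata(dataio.read_table(d / "metadata.tsv", "metadata"))
    frames = []
    for grp in CONTRASTS:
        if (meta.table["group"] == grp).sum() >= 3:
            frames.append(signatures.differential_metabolites(prep, meta, (grp, "NGT")))
    out = pd.concat(frames, ignore_index=True)
    print(f"{cohort}: {int(out['significant'].sum())} significant calls "
          f"over {out['comparison'].nunique()} contrasts")
    return out


def main() -> None:
    disc = call_cohort("cohort_discovery")
    val = call_cohort("cohort_validation")
    disc.to_csv(RESULTS / "signatures_discovery.tsv", sep="\t", index=False, float_format="%.10g")
    val.to_csv(RESULTS / "signatures_validation.tsv", sep="\t", index=False, float_format="%.10g")

    consistent = signatures.consistent_signatures(disc, val)
    consistent.to_csv(RESULTS / "signatures_consistent.tsv", sep="\t", index=False,
                      float_format="%.10g")
    sig_set = set(consistent["metabolite_id"])
    print(f"consistent signatures (both cohorts, same direction): {len(sig_set)} unique")

    # age/sex-adjusted odds ratios, CGI/T2D vs NGT, discovery cohort
    d = RESULTS / "cohort_discovery"
    prep = dataio.read_table(d / "metabolites_preprocessed.tsv", "features")
    meta = dataio.read_table(d / "metadata.tsv", "metadata")
    is_case = meta["group"].isin(["CGI", "T2D"]).to_numpy()
    keep = is_case | (meta["group"] == "NGT").to_numpy()
    rows = []
    for met in prep.columns:
        res = signatures.adjusted_odds_ratio(
            is_case[keep].astype(float),
            prep[met].to_numpy()[keep],
            meta["age"].to_numpy(dtype=float)[keep],
            meta["sex"].to_numpy(dtype=float)[keep],
            metabolite_id=met,
            outcome="CGI_T2D_vs_NGT",
        )
        rows.append(res)
    ors = pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in rows],
            "or_per_sd": [r.or_value for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p": [r.p for r in rows],
            "separation": [r.separation for r in rows],
        }
    )
    from micromet.ev import compute_qvalues

    ok = ~ors["p"].isna()
    ors.loc[ok, "q"] = compute_qvalues(ors.loc[ok, "p"].to_numpy())[0]
    ors.to_csv(RESULTS / "odds_ratios.tsv", sep="\t", index=False, float_format="%.10g")
    n_or = int((ors["q"] < 0.1).sum())
    print(f"odds ratios: {n_or} metabolites at q < 0.1")

    # overlap of per-contrast significant sets + proportion test
    sets = {
        c: set(disc.loc[(disc["comparison"] == f"{c}_vs_NGT") & disc["significant"],
                        "metabolite_id"])
        for c in CONTRASTS
    }
    sets = {k: v for k, v in sets.items() if v}
    if len(sets) >= 2:
        overlap = signatures.overlap_summary(sets)
        overlap.to_csv(RESULTS / "signature_overlap.tsv", sep="\t", index=False)
        print("overlap regions:", dict(zip(overlap["region"], overlap["count"])))

    # response-code clustering of the consistent signatures
    if sig_set:
        codes = []
        for met in sorted(sig_set):
            row = {}
            for c in CONTRASTS:
                sub = disc[(disc["metabolite_id"] == met) &
                           (disc["comparison"] == f"{c}_vs_NGT")]
                row[c] = int(sub["effect_direction"].iloc[0] * sub["significant"].iloc[0]) \
                    if len(sub) else 0
            codes.append(row)
        eff = pd.DataFrame(codes, index=sorted(sig_set))
        k = min(8, len(np.unique(eff.to_numpy(), axis=0)))
        labels = signatures.cluster_responses(eff, k=k)
        labels.to_frame().to_csv(RESULTS / "signature_clusters.tsv", sep="\t")
        print(f"response clustering: {labels.nunique()} clusters over {len(eff)} signatures")


if __name__ == "__main__":
    main()
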