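#!/usr/bin/env python
"""Classification and regression benchmarks on the synthetic cohorts.

Random-forest CV classifier separating CGI/T2D from NGT using (a) all
metabolites and (b) the microbiome table; a random-forest regressor
predicting the Shannon diversity index from metabolites vs clinical
features; and the concordance between tree-model attributions and ridge
coefficients on the same target.  Writes results/classifiers.json.
"""

import json
from pathlib import Path

import numpy as np

from micromet import attribution, classify, dataio, ev
from micromet.cli import _read_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    d = RESULTS / "cohort_discovery"
    bundle = _read_bundle(d)
    prep = dataio.read_table(d / "metabolites_preprocessed.tsv", "features")
    meta = dataio.read_table(d / "metadata.tsv", "metadata")
    out: dict = {}

    is_case = meta["group"].isin(["CGI", "T2D"]).to_numpy()
    keep = is_case | (meta["group"] == "NGT").to_numpy()
    y = is_case[keep].astype(int)
    for name, X in (
        ("metabolites", prep.to_numpy()[keep]),
        ("microbiome", ev.assemble_design(bundle)["microbiome"][keep]),
    ):
        cv, _ = classify.rf_cv_classifier(X, y, n_trees=500, folds=5, repeats=2, seed=7)
        out[f"auc_{name}"] = cv.mean_metric
        print(f"CGI/T2D vs NGT from {name}: CV AUC {cv.mean_metric:.3f} "
              f"(+/- {cv.se_metric:.3f})")

    # Shannon diversity predicted from metabolites vs clinical features
    shannon = dataio.shannon_per_sample(bundle.microbiome).to_numpy()
    for name, X in (
        ("metabolites", prep.to_numpy()),
        ("clinical", bundle.clinical.to_numpy(dtype=float)),
    ):
        cv = classify.rf_cv_regressor(X, shannon, n_trees=300, folds=5, repeats=2, seed=8)[0]
        out[f"shannon_r2_{name}"] = cv.mean_metric
        print(f"Shannon index from {name}: mean out-of-sample R2 {cv.mean_metric:.3f}")

    # attribution-vs-ridge concordance on the strongest metabolite target
    target = prep.columns[0]
    yv = prep[target].to_numpy()
    X = ev.assemble_design(bundle)["microbiome"]
    model = ev.fit_gbdt(X, yv, spec=ev.GBDTSpec(n_search=3), seed=9)
    am = attribution.attribution_values(model, X)
    signed = attribution.signed_importance(am, X)
    ridge = classify.ridge_adjusted(
        X, yv, meta[["age", "sex"]].to_numpy(dtype=float), seed=10
    )
    conc = classify.importance_concordance(signed, ridge.coefficients)
    out["shap_ridge_pearson_r"] = conc["pearson_r"]
    print(f"attribution vs ridge concordance on {target}: "
          f"R = {conc['pearson_r']:.2f} (P = {conc['pearson_p']:.2g})")

    (RESULTS / "classifiers.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
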