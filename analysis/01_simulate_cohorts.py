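#!/usr/bin/env python
"""Generate the discovery and validation cohorts used by all later steps.

Two independent synthetic cohorts (n=300 and n=200) share the same planted
structure: a keystone MGS driving ten metabolites, clinical-, diet- and
mixed-signal metabolites, glucose-status labels with standardized shifts
planted in the CGI and T2D groups.  Tables are written as TSV under
results/cohort_discovery/ and results/cohort_validation/, each with a
ground-truth JSON sidecar (read only by tests, never by analysis).
"""

from pathlib import Path

from micromet import pipeline, synthgen

RESULTS = Path(__file__).resolve().parent.parent / "results"


def make_cohort(n: int, seed: int, out: Path) -> None:
    sim = dict(pipeline.DEFAULT_CONFIG["simulate"], n=n)
    bundle = synthgen.gen_feature_bundle(
        n, sim["p_clinical"], sim["p_microbiome"], sim["p_diet"],
        zero_inflation=sim["zero_inflation"], seed=seed,
    )
    plan = pipeline._signal_plan(sim)
    std, truth = synthgen.gen_metabolite_matrix(bundle, plan, seed=seed + 1)
    raw = synthgen.to_raw_abundance_scale(std, seed=seed + 2)
    shifts = {m: {"T2D": 0.8, "CGI": 0.5} for m in list(raw.columns)[:6]}
    meta, raw, truth_lab = synthgen.gen_cohort_labels(
        n, raw, planted_shifts=shifts, seed=seed + 3
    )
    truth.differential = truth_lab.differential
    files = synthgen.write_cohort(out, bundle, raw, meta, truth)
    print(f"{out.name}: n={n}, wrote {len(files)} files")


def main() -> None:
    make_cohort(300, seed=11, out=RESULTS / "cohort_discovery")
    make_cohort(200, seed=47, out=RESULTS / "cohort_validation")


if __name__ == "__main__":
    main()
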