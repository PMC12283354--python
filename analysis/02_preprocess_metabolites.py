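#!/usr/bin/env python
"""Apply the metabolite preprocessing chain to both cohorts.

Per cohort: metabolites with fewer than ten measurements are dropped, the
rest log10-transformed, missing cells imputed with the column minimum and
each column standardized.  Writes results/<cohort>/metabolites_preprocessed.tsv
and prints the drop report.
"""

from pathlib import Path

from micromet import dataio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for cohort in ("cohort_discovery", "cohort_validation"):
        raw = dataio.read_table(RESULTS / cohort / "metabolites.tsv", "metabolites")
        prep, report = dataio.preprocess_metabolites(raw)
        out = RESULTS / cohort / "metabolites_preprocessed.tsv"
        prep.values.to_csv(out, sep="\t", index_label="sample_id", na_rep="NA")
        print(
            f"{cohort}: kept {report.n_kept}/{report.n_raw} metabolites "
            f"(dropped {len(report.dropped_few_measurements)} under-measured, "
            f"{len(report.dropped_constant)} constant)"
        )


if __name__ == "__main__":
    main()
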