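#!/usr/bin/env python
"""Statistical validation battery for the inference machinery.

Runs the planted-truth simulation experiments — Wald-test null calibration,
planted-EV recovery, relative-power ordering, keystone recovery, mediation
coverage, classifier sanity and the exact-statistic oracles — and writes
results/method_validation.json.  Sizes here are moderate; the test suite
runs the same experiments at full size.
"""

import json
from pathlib import Path

from micromet import experiments

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = {}
    print("null calibration (100 replicates) ...")
    out["null_calibration"] = experiments.ev_null_calibration(seed=1, n_replicates=100)
    print("  rejection rate:", out["null_calibration"]["rejection_rate"])
    print("planted-EV recovery (5 seeds) ...")
    out["ev_recovery"] = experiments.ev_recovery(seed=2, n_seeds=5)
    print("  median:", round(out["ev_recovery"]["median_r2"], 3))
    print("relative-power ordering (10 seeds) ...")
    out["relative_power"] = experiments.relative_power_ordering(seed=3, n_seeds=10)
    print("  ordering rate:", out["relative_power"]["ordering_rate"])
    print("keystone recovery (10 seeds) ...")
    out["keystone"] = experiments.keystone_recovery(seed=4, n_seeds=10)
    print("  top-rank rate:", out["keystone"]["top_rank_rate"])
    print("mediation coverage (100 sims) ...")
    out["mediation_coverage"] = experiments.mediation_coverage(seed=5, n_sims=100)
    print("  coverage:", out["mediation_coverage"]["coverage"])
    print("classifier sanity (10 null seeds) ...")
    clf = experiments.classifier_sanity(seed=6, n_null_seeds=10)
    out["classifier"] = {k: v for k, v in clf.items() if k != "null_aucs"}
    print("  planted AUC:", round(clf["planted_auc"], 3),
          "null mean:", round(clf["null_auc_mean"], 3))
    out["exact_oracles"] = experiments.exact_statistic_oracles()
    out["centrality_oracle"] = experiments.centrality_oracle(seed=7, n_graphs=100)
    out["preprocessing_toy"] = experiments.preprocessing_toy()
    (RESULTS / "method_validation.json").write_text(json.dumps(out, indent=1, sort_keys=True))
    print("wrote results/method_validation.json")


if __name__ == "__main__":
    main()
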