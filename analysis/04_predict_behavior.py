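#!/usr/bin/env python
"""Predict the behavioral score from complexity features.

For each measure (nMSE, edge-based nMSE, eMSE): assemble the subject x
(unit, scale) feature matrix, run leave-one-subject-out linear SVR with
correlation-ranked feature selection inside each fold, and assess the
predicted-vs-actual correlation with a permutation test.
"""

import json
from pathlib import Path

import pandas as pd

from brainmse import assemble_features, loso_svr_predict, permutation_test
from brainmse.io import read_cohort, write_tables

ROOT = Path(__file__).resolve().parent.parent / "results"
N_FEATURES = 20
N_PERMUTATIONS = 99
SEED = 1
TABLES = {"nMSE": "nmse", "edge_based_nMSE": "edge_based_nmse", "eMSE": "emse"}


def main() -> None:
    _, _, scores_df, _ = read_cohort(ROOT / "cohort" / "manifest.json")
    report = {}
    rows = []
    for measure, stem in TABLES.items():
        table = pd.read_csv(ROOT / "complexity" / f"{stem}.tsv", sep="\t",
                            dtype={"unit": str})
        scales = sorted(table["scale"].unique())
        X, dropped = assemble_features(table, measure, scales)
        y = scores_df.set_index("subject").loc[list(X.index), "score"].to_numpy()
        res = loso_svr_predict(X, y, N_FEATURES)
        perm = permutation_test(X, y, N_FEATURES, n_permutations=N_PERMUTATIONS,
                                seed=SEED)
        report[measure] = {
            "n_features": res.n_features,
            "n_dropped": len(dropped),
            "observed_r": res.r,
            "permutation_p": perm.p_value,
            "common_features": res.common_features,
        }
        rows.append(pd.DataFrame({
            "measure": measure,
            "subject": res.subjects,
            "actual": res.actual,
            "predicted": res.predictions,
        }))
        print(f"{measure:>16}: {X.shape[1]} features ({len(dropped)} dropped), "
              f"LOSO r = {res.r:.3f}, permutation p = {perm.p_value:.3f} "
              f"(B = {N_PERMUTATIONS}); {len(res.common_features)} features "
              f"common to all folds")
    write_tables({"predictions": pd.concat(rows, ignore_index=True)},
                 ROOT / "prediction")
    (ROOT / "prediction" / "report.json").write_text(json.dumps(report, indent=1))
    print(f"wrote prediction report to {ROOT / 'prediction'}")


if __name__ == "__main__":
    main()
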