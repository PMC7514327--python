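"""Canonical end-to-end experiments on synthetic cohorts.

Defines the study conditions used by the analysis drivers and the
verification suite: a planted cohort of 60 subjects with 20 nodes and
four 300-point runs, node entropy computed at the operating point
m = 3, r = 0.2 over scale factors 1-10, 50 features selected in each
leave-one-subject-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortSpec, SyntheticCohort, generate_cohort
from .entropy import EntropyParams
from .mapping import node_mse_table
from .prediction import assemble_features, loso_svr_predict, permutation_test
from .preprocess import preprocess_runs

__all__ = ["planted_cohort_spec", "planted_features", "recovery_experiment"]

OPERATING_POINT = EntropyParams(m=3, r=0.2, scales=tuple(range(1, 11)))


def planted_cohort_spec(seed: int) -> CohortSpec:
    """The planted recovery cohort: 60 subjects, 20 nodes, 4 x 300 points."""
    return CohortSpec(
        n_subjects=60,
        n_nodes=20,
        n_runs=4,
        run_length=300,
        planted_nodes=(1, 2, 3, 4),
        seed=seed,
    )


def planted_features(
    seed: int, params: EntropyParams = OPERATING_POINT
) -> tuple[pd.DataFrame, np.ndarray, SyntheticCohort]:
    """Generate a planted cohort and compute its node-entropy feature matrix.

    Runs the full stack: generation, per-run detrend/z-score/concatenate,
    multiscale node entropy, cohort-wide assembly with failed features
    dropped.  Returns (features, scores, cohort).
    """
    cohort = generate_cohort(planted_cohort_spec(seed))
    signals = {
        s + 1: preprocess_runs(runs, subject=s + 1)
        for s, runs in enumerate(cohort.node_signals)
    }
    nmse = node_mse_table(signals, params)
    X, _ = assemble_features(nmse, "nMSE", params.scales)
    return X, cohort.scores, cohort


@dataclass
class RecoveryResult:
    seeds: list[int]
    r_values: list[float]
    median_r: float
    permutation_p: float
    permutation_seed: int


def recovery_experiment(
    seeds: list[int], n_features: int = 50, n_permutations: int = 99
) -> RecoveryResult:
    """Planted-signal recovery across generator seeds.

    Runs the full pipeline per seed and reports the per-seed LOSO
    predicted-vs-actual correlations and their median; the permutation
    test (B permutations) is evaluated on the median-r seed's cohort, the
    representative pipeline result.
    """
    r_values = []
    cached: dict[int, tuple[pd.DataFrame, np.ndarray]] = {}
    for seed in seeds:
        X, y, _ = planted_features(seed)
        cached[seed] = (X, y)
        r_values.append(loso_svr_predict(X, y, n_features).r)
    order = np.argsort(r_values)
    median_seed = seeds[order[len(seeds) // 2]]
    X, y = cached[median_seed]
    perm = permutation_test(X, y, n_features, n_permutations=n_permutations, seed=median_seed)
    return RecoveryResult(
        seeds=list(seeds),
        r_values=r_values,
        median_r=float(np.median(r_values)),
        permutation_p=perm.p_value,
        permutation_seed=median_seed,
    )
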