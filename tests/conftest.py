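import numpy as np
import pytest

from brainmse import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by mapping/prediction tests."""
    spec = CohortSpec(
        n_subjects=12,
        n_nodes=6,
        n_runs=2,
        run_length=200,
        planted_nodes=(1, 2),
        n_csf_signals=3,
        seed=11,
    )
    return generate_cohort(spec)


def brute_force_match_counts(x, m, tol):
    """Independent O(N^2) SampEn match-count oracle (numpy broadcasting).

    Templates of lengths m and m+1 both start at the first N-m points;
    pairs i < j match when the Chebyshev distance is <= tol.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    nt = n - m
    idx = np.arange(nt)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]  # nt x (m+1)
    diff = np.abs(templates[:, None, :] - templates[None, :, :])  # nt x nt x (m+1)
    upper = np.triu(np.ones((nt, nt), dtype=bool), k=1)
    match_m = (diff[:, :, :m].max(axis=2) <= tol) & upper
    match_m1 = (diff.max(axis=2) <= tol) & upper
    return int(match_m1.sum()), int(match_m.sum())
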