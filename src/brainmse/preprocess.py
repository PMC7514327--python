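"""Preprocessing contract: per-run detrend, z-score, concatenate.

Each run's node signals are linearly detrended (least-squares fit
removal) and z-scored per node, then the runs are concatenated along
time — e.g. four 1200-point runs yield one 4800-point series per node.
No filtering is applied at any point.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import detrend

__all__ = ["preprocess_runs"]


def preprocess_runs(
    runs: Sequence[np.ndarray], subject: object = None
) -> np.ndarray:
    """Detrend and z-score each run per node, then concatenate along time.

    Z-scoring uses the sample standard deviation (ddof = 1).  A node with
    zero variance after detrending (e.g. a constant or pure linear ramp)
    is an error naming the subject, run, and node.
    """
    runs = [np.atleast_2d(np.asarray(r, dtype=float)) for r in runs]
    if not runs:
        raise ValueError("no runs provided")
    n_nodes = runs[0].shape[0]
    if any(r.shape[0] != n_nodes for r in runs):
        raise ValueError("all runs must share the same node count")
    out = []
    who = f"subject {subject} " if subject is not None else ""
    for run_idx, run in enumerate(runs, start=1):
        det = detrend(run, axis=1, type="linear")
        sd = det.std(axis=1, ddof=1)
        # a pure ramp detrends to floating-point dust, not exact zeros
        tol = 1e-12 * (1.0 + np.ptp(run, axis=1))
        bad = np.flatnonzero(sd <= tol)
        if bad.size:
            raise ValueError(
                f"{who}run {run_idx} node {bad[0] + 1}: zero variance after detrending"
            )
        out.append((det - det.mean(axis=1, keepdims=True)) / sd[:, None])
    return np.concatenate(out, axis=1)
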