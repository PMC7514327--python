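"""Instantaneous phase and BOLD phase-coherence dynamic connectivity.

The instantaneous phase of each node signal is the angle of its analytic
signal (Hilbert transform).  Phase-coherence connectivity between nodes
``i`` and ``j`` at time ``t`` is

    dFC(i, j, t) = cos(theta_i(t) - theta_j(t))

which is 1 for in-phase nodes, -1 in antiphase, and 0 in quadrature.
Since the frame matrix is symmetric with unit diagonal, only the upper
triangle carries information: ``n`` nodes yield ``n (n - 1) / 2`` edge
time series, indexed in row-major upper-triangular order with 1-based
node ids.

No band-pass filtering is applied before phase extraction; the signals
are used as delivered by preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PhaseArray",
    "EdgeSeriesSet",
    "edge_index",
    "instantaneous_phase",
    "pcc_frame",
    "edge_series_from_nodes",
    "reconstruct_frame",
]


@dataclass
class PhaseArray:
    """Node x time matrix of instantaneous phases, wrapped to (-pi, pi]."""

    theta: np.ndarray


@dataclass
class EdgeSeriesSet:
    """Edge x time matrix of phase-coherence values with a canonical index.

    ``edge_index[k]`` is the 1-based node pair ``(i, j)``, ``i < j``, of
    row ``k``; pairs are ordered row-major over the upper triangle:
    (1,2), (1,3), ..., (1,n), (2,3), ...
    """

    edge_values: np.ndarray
    edge_index: list[tuple[int, int]]
    n_nodes: int


def edge_index(n_nodes: int) -> list[tuple[int, int]]:
    """Canonical 1-based (i, j) pairs, i < j, row-major upper triangular."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    return [(i, j) for i in range(1, n_nodes + 1) for j in range(i + 1, n_nodes + 1)]


def instantaneous_phase(signals: np.ndarray) -> PhaseArray:
    """Per-node instantaneous phase of the analytic signal.

    Raises if any node signal has zero variance (phase undefined) or the
    series is shorter than 16 samples.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    if signals.shape[1] < 16:
        raise ValueError(
            f"need at least 16 time points for phase extraction, got {signals.shape[1]}"
        )
    variances = signals.var(axis=1)
    flat = np.flatnonzero(variances == 0)
    if flat.size:
        raise ValueError(
            f"node {flat[0] + 1} has zero variance; instantaneous phase undefined"
        )
    theta = np.angle(hilbert(signals, axis=1))
    return PhaseArray(theta=theta)


def pcc_frame(theta_t: np.ndarray) -> np.ndarray:
    """Phase-coherence matrix cos(theta_i - theta_j) for one time frame.

    Symmetric with unit diagonal; entries in [-1, 1].
    """
    theta_t = np.asarray(theta_t, dtype=np.float64).ravel()
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("phases must be finite")
    return np.cos(theta_t[:, None] - theta_t[None, :])


def edge_series_from_nodes(signals: np.ndarray, trim: int = 0) -> EdgeSeriesSet:
    """Phase-coherence edge time series from a node x time signal matrix.

    Applies :func:`instantaneous_phase`, evaluates the per-frame coherence,
    and extracts the upper triangle in canonical order.  ``trim`` drops
    that many samples from each end of the phase series before the edge
    computation (analytic-signal edge effects); default keeps everything.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    n = signals.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    theta = instantaneous_phase(signals).theta
    if trim:
        if 2 * trim >= theta.shape[1]:
            raise ValueError(f"trim {trim} leaves no samples")
        theta = theta[:, trim:-trim]
    rows, cols = np.triu_indices(n, k=1)
    edge_values = np.cos(theta[rows] - theta[cols])
    return EdgeSeriesSet(
        edge_values=edge_values,
        edge_index=edge_index(n),
        n_nodes=n,
    )


def reconstruct_frame(edge_values_t: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the full symmetric unit-diagonal matrix of one time frame."""
    mat = np.eye(n_nodes)
    rows, cols = np.triu_indices(n_nodes, k=1)
    mat[rows, cols] = edge_values_t
    mat[cols, rows] = edge_values_t
    return mat
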