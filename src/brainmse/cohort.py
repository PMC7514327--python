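"""Synthetic multi-subject cohort generator.

Emulates the statistical structure the downstream analysis assumes about
resting-state BOLD data, without any imaging forward model:

* per run, each node signal is a mixture
  ``(1 - lambda_s) * (oscillator + pink) + lambda_s * white`` where the
  oscillator is a band-limited (default 0.01-0.1 Hz) stochastic
  oscillation shared by all nodes of a resting-state network (random
  spectrum per subject, network, and run — hence random phase), the pink
  component is 1/f-shaped background noise private to the node, and
  ``white`` is i.i.d. Gaussian noise;
* the per-subject mixing weight ``lambda_s`` of *planted* nodes is drawn
  from ``noise_fraction_range``, while every other node uses the range
  midpoint — so only planted nodes carry between-subject entropy
  variation;
* CSF reference signals are pure i.i.d. Gaussian white noise, matching
  the role of cerebrospinal-fluid series as a minimal-physiology noise
  reference;
* the behavioral score is a noisy linear function of the planted nodes'
  ``lambda_s``.  Coupling the score to the mixing weight (and not to any
  computed entropy) keeps the generator independent of the estimators it
  is used to test: more white noise means higher sample entropy, so the
  score is entropy-coupled only through the ground-truth physics.

Identical seeds reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .atlas import RsnAtlas, stanford_atlas, uniform_atlas

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_node_signals",
    "generate_csf_signals",
    "generate_behavior_scores",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the geometry of four ~15-minute resting-state runs at
    0.72 s sampling with 90 nodes; analyses and tests use reduced sizes.
    """

    n_subjects: int = 20
    n_nodes: int = 90
    n_runs: int = 4
    run_length: int = 1200
    sampling_interval: float = 0.72
    atlas: RsnAtlas | None = None
    oscillator_band: tuple[float, float] = (0.01, 0.1)
    pink_exponent: float = 1.0
    planted_nodes: tuple[int, ...] = (1, 2, 3, 4)
    noise_fraction_range: tuple[float, float] = (0.2, 0.8)
    score_noise_sd: float = 0.1
    n_csf_signals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if self.run_length < 100:
            raise ValueError(f"run_length must be >= 100, got {self.run_length}")
        if self.n_subjects < 1 or self.n_runs < 1 or self.n_csf_signals < 1:
            raise ValueError("counts must be positive")
        nyquist = 0.5 / self.sampling_interval
        lo, hi = self.oscillator_band
        if not (0 < lo < hi < nyquist):
            raise ValueError(
                f"oscillator band {self.oscillator_band} must lie inside "
                f"(0, Nyquist={nyquist:.4g}) Hz"
            )
        bad = [p for p in self.planted_nodes if not 1 <= p <= self.n_nodes]
        if bad:
            raise ValueError(f"planted nodes {bad} outside 1..{self.n_nodes}")
        a, b = self.noise_fraction_range
        if not (0 <= a <= b <= 1):
            raise ValueError(
                f"noise_fraction_range {self.noise_fraction_range} must be within [0, 1]"
            )
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be non-negative")
        if self.atlas is not None and self.atlas.n_nodes != self.n_nodes:
            raise ValueError("atlas node count does not match n_nodes")

    def resolved_atlas(self) -> RsnAtlas:
        if self.atlas is not None:
            return self.atlas
        if self.n_nodes == 90:
            return stanford_atlas()
        return uniform_atlas(self.n_nodes)

    @property
    def total_length(self) -> int:
        return self.n_runs * self.run_length


@dataclass
class SyntheticCohort:
    """A generated cohort: signals, CSF references, scores, and ground truth.

    ``node_signals[s]`` is a list of ``n_runs`` node x time matrices for
    subject ``s`` (0-based subject positions); ``truth`` records the
    mixing weights, planted nodes, and score weights actually used.
    """

    spec: CohortSpec
    node_signals: list[list[np.ndarray]]
    csf_signals: list[np.ndarray] = field(default_factory=list)
    scores: np.ndarray | None = None
    truth: dict[str, Any] = field(default_factory=dict)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise, variance-normalized."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_limited_oscillation(
    rng: np.random.Generator, n: int, dt: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance stochastic oscillation confined to ``band`` (Hz).

    Built by masking the spectrum of white noise to the band, so the
    phases of the retained components are random.
    """
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():  # band narrower than the frequency resolution
        mask[np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))] = True
    x = np.fft.irfft(spectrum * mask, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _mixing_weights(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-subject, per-node white-noise weights lambda_s (subjects x nodes)."""
    lo, hi = spec.noise_fraction_range
    lambdas = np.full((spec.n_subjects, spec.n_nodes), 0.5 * (lo + hi))
    planted = np.asarray(spec.planted_nodes, dtype=int) - 1
    lambdas[:, planted] = rng.uniform(lo, hi, size=(spec.n_subjects, planted.size))
    return lambdas


def generate_node_signals(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[list[list[np.ndarray]], np.ndarray]:
    """Node signals for all subjects and runs, plus the lambda truth matrix.

    Each run is statistically independent given the subject's mixing
    weights; nodes within a resting-state network share the run's
    oscillator realization.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    atlas = spec.resolved_atlas()
    lambdas = _mixing_weights(spec, rng)
    node_nets = [atlas.membership[i] for i in range(1, spec.n_nodes + 1)]
    subjects: list[list[np.ndarray]] = []
    for s in range(spec.n_subjects):
        runs: list[np.ndarray] = []
        for _ in range(spec.n_runs):
            oscillators = {
                net: _band_limited_oscillation(
                    rng, spec.run_length, spec.sampling_interval, spec.oscillator_band
                )
                for net in atlas.network_names
            }
            run = np.empty((spec.n_nodes, spec.run_length))
            for node in range(spec.n_nodes):
                lam = lambdas[s, node]
                structured = oscillators[node_nets[node]] + _pink_noise(
                    rng, spec.run_length, spec.pink_exponent
                )
                white = rng.standard_normal(spec.run_length)
                run[node] = (1.0 - lam) * structured + lam * white
            runs.append(run)
        subjects.append(runs)
    return subjects, lambdas


def generate_csf_signals(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Per-subject CSF reference matrices: i.i.d. Gaussian white noise.

    Each subject gets ``n_csf_signals`` series whose length equals the
    concatenated node-run length.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    return [
        rng.standard_normal((spec.n_csf_signals, spec.total_length))
        for _ in range(spec.n_subjects)
    ]


def generate_behavior_scores(
    lambdas: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Behavioral scores linearly coupled to the planted nodes' lambdas.

    ``score_s = sum_k w_k * lambda_s(planted node k) + eps_s`` with
    ``eps_s ~ Normal(0, score_noise_sd)``.  Returns (scores, weights);
    weights default to all ones.
    """
    if len(spec.planted_nodes) == 0:
        raise ValueError("planted_nodes must be non-empty to generate scores")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    planted = np.asarray(spec.planted_nodes, dtype=int) - 1
    if weights is None:
        weights = np.ones(planted.size)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (planted.size,):
        raise ValueError("one weight per planted node required")
    signal = lambdas[:, planted] @ weights
    noise = (
        rng.normal(0.0, spec.score_noise_sd, size=signal.size)
        if spec.score_noise_sd > 0
        else np.zeros(signal.size)
    )
    return signal + noise, weights


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort (signals, CSF, scores, truth) from one seed."""
    rng = np.random.default_rng(spec.seed)
    node_signals, lambdas = generate_node_signals(spec, rng)
    csf = generate_csf_signals(spec, rng)
    scores, weights = generate_behavior_scores(lambdas, spec, rng)
    truth = {
        "lambdas": lambdas,
        "planted_nodes": tuple(spec.planted_nodes),
        "score_weights": weights,
        "score_noise_sd": spec.score_noise_sd,
    }
    return SyntheticCohort(
        spec=spec,
        node_signals=node_signals,
        csf_signals=csf,
        scores=scores,
        truth=truth,
    )
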