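"""Coarse-graining, sample entropy (SampEn), and multiscale entropy (MSE).

Sample entropy of a series ``x`` of length ``N`` is

    SampEn(m, r, N) = -ln( A / B )

where ``B`` counts ordered-distinct pairs of length-``m`` templates whose
Chebyshev (maximum-coordinate) distance is at most ``r * SD``, and ``A``
counts the corresponding length-``m + 1`` pairs.  Self-matches are excluded
and both template sets start at the first ``N - m`` points, so the two
counts range over a common pair index set.  Higher SampEn means a less
predictable, more complex signal.

Multiscale entropy evaluates SampEn on successively coarse-grained copies
of the series: scale factor ``l`` replaces non-overlapping blocks of ``l``
consecutive points by their mean, yielding a series of length
``floor(N / l)``.  The tolerance is *scale-invariant*: the standard
deviation is computed once on the scale-1 series and reused at every
scale, so coarse-graining (which shrinks the variance of noise-like
signals) drives SampEn of white noise down with scale.

Failure handling: when no template pair matches at either length the
ratio is undefined.  :func:`sample_entropy` returns NaN in that case and
:func:`mse_profile` records a per-scale boolean ``failed`` mask; failures
are data, never exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import erf

__all__ = [
    "EntropyParams",
    "MseProfile",
    "coarse_grain",
    "template_match_counts",
    "sample_entropy",
    "mse_profile",
    "iid_gaussian_sampen_oracle",
]


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of a multiscale-entropy computation.

    Attributes
    ----------
    m : int
        Pattern length (number of consecutive points compared), >= 1.
    r : float
        Tolerance as a fraction of the scale-1 standard deviation, > 0.
    scales : tuple of int
        Strictly increasing scale factors, each >= 1.
    """

    m: int = 3
    r: float = 0.2
    scales: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if int(self.m) < 1:
            raise ValueError(f"pattern length m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")
        scales = tuple(int(s) for s in self.scales)
        if len(scales) == 0:
            raise ValueError("scales must be non-empty")
        if scales[0] < 1 or any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(
                f"scales must be strictly increasing positive integers, got {scales}"
            )
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "r", float(self.r))
        object.__setattr__(self, "scales", scales)


@dataclass
class MseProfile:
    """SampEn per scale factor with a per-scale failure mask.

    ``values[k]`` is the SampEn of the scale ``params.scales[k]``
    coarse-grained series (NaN where ``failed[k]`` is True); ``n_points``
    is the length of the original scale-1 series.
    """

    values: np.ndarray
    failed: np.ndarray
    params: EntropyParams
    n_points: int


def coarse_grain(x: np.ndarray, l: int) -> np.ndarray:
    """Average non-overlapping blocks of ``l`` consecutive points.

    Returns a series of length ``floor(len(x) / l)``; trailing points that
    do not fill a block are discarded.  ``l == 1`` returns a copy of the
    input.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    l = int(l)
    if l < 1:
        raise ValueError(f"scale factor must be >= 1, got {l}")
    if l > x.size:
        raise ValueError(
            f"scale factor {l} exceeds series length {x.size}: scale unusable"
        )
    n_blocks = x.size // l
    return x[: n_blocks * l].reshape(n_blocks, l).mean(axis=1)


@njit(cache=True)
def _match_counts(x, m, tol):  # pragma: no cover - exercised via wrapper
    n = x.shape[0]
    nt = n - m  # templates start at 0 .. nt-1; m- and (m+1)-templates both defined
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > tol:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    return a, b


def template_match_counts(
    x: np.ndarray, m: int, r: float, sd_ref: float | None = None
) -> tuple[int, int]:
    """Return ``(A, B)``: the (m+1)- and m-length template match counts.

    Pairs ``i < j`` of templates drawn from the first ``N - m`` starting
    points match when their Chebyshev distance is ``<= r * SD``
    (inclusive), with ``SD = sd_ref`` if given else the sample standard
    deviation of ``x``.
    """
    x = np.ascontiguousarray(x, dtype=np.float64).ravel()
    m = int(m)
    if m < 1:
        raise ValueError(f"pattern length m must be >= 1, got {m}")
    if not r > 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    if x.size < m + 2:
        raise ValueError(
            f"series length {x.size} too short for pattern length {m} (need >= {m + 2})"
        )
    sd = float(np.std(x)) if sd_ref is None else float(sd_ref)
    if sd < 0:
        raise ValueError("reference standard deviation must be non-negative")
    a, b = _match_counts(x, m, r * sd)
    return int(a), int(b)


def sample_entropy(
    x: np.ndarray, m: int = 3, r: float = 0.2, sd_ref: float | None = None
) -> float:
    """Sample entropy of a 1-D series; NaN flags an estimation failure.

    Parameters
    ----------
    x : array-like
        Input series, length > m + 1.
    m : int
        Pattern length.
    r : float
        Tolerance as a fraction of the standard deviation.
    sd_ref : float, optional
        Reference standard deviation defining the tolerance ``r * sd_ref``.
        Defaults to the sample standard deviation of ``x``; passing the
        scale-1 SD here makes the tolerance scale-invariant across a
        multiscale computation.

    Returns
    -------
    float
        ``-ln(A / B)``, or NaN when either match count is zero (no
        matching patterns found — the combination fails, as happens for
        small tolerances and long patterns).
    """
    a, b = template_match_counts(x, m, r, sd_ref=sd_ref)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def mse_profile(
    x: np.ndarray, params: EntropyParams, sd_ref: float | None = None
) -> MseProfile:
    """Multiscale entropy of a series with scale-invariant tolerance.

    For each scale factor the series is coarse-grained and SampEn is
    computed with the tolerance anchored to the scale-1 standard
    deviation (``sd_ref`` if given, else ``std(x)``).  Per-scale
    estimation failures are recorded in the ``failed`` mask and never
    raised.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    max_scale = max(params.scales)
    if x.size < max_scale * (params.m + 2):
        raise ValueError(
            f"series length {x.size} too short for scale {max_scale} with m={params.m}"
        )
    sd = float(np.std(x)) if sd_ref is None else float(sd_ref)
    values = np.full(len(params.scales), np.nan)
    failed = np.zeros(len(params.scales), dtype=bool)
    for k, l in enumerate(params.scales):
        y = coarse_grain(x, l)
        v = sample_entropy(y, params.m, params.r, sd_ref=sd)
        values[k] = v
        failed[k] = math.isnan(v)
    return MseProfile(values=values, failed=failed, params=params, n_points=x.size)


def iid_gaussian_sampen_oracle(r: float, l: int = 1) -> float:
    """Predicted SampEn of i.i.d. Gaussian noise at scale ``l``.

    Coarse-graining i.i.d. noise divides its variance by ``l`` while the
    scale-invariant tolerance ``r * SD(scale 1)`` is fixed, so the
    per-coordinate match probability of two independent coarse-grained
    points is ``erf(r * sqrt(l) / 2)`` and coordinates are independent,
    giving ``SampEn = -ln erf(r * sqrt(l) / 2)`` for any pattern length.
    Decreases monotonically to 0 as ``l`` grows.
    """
    if not r > 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    if int(l) < 1:
        raise ValueError(f"scale factor must be >= 1, got {l}")
    return float(-np.log(erf(r * math.sqrt(l) / 2.0)))
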