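"""Relative-error mapping of the acceptable SampEn parameter space.

The tolerance / pattern-length grid is screened against reference CSF
signals: for each subject and each (m, r, scale) cell, SampEn is computed
for every CSF series of that subject, and the relative error is derived
from the mean and standard deviation of those SampEn values.  The median
across subjects makes the surface; a cell where any subject fails to
estimate SampEn (no matching patterns) is marked failed and carries no
value.  Combinations whose mean relative error across scales stays at or
below the threshold (default 0.1, about a 10% coefficient of variation)
and that never fail form the acceptable parameter space.

The printed form of the relative-error formula is ambiguous about where
the square sits; all three readings are available and the chosen variant
is recorded in every output:

* ``literal``  — RE = 1.96 * sigma / mu**2   (default)
* ``ratio``    — RE = 1.96 * sigma / mu
* ``squared``  — RE = (1.96 * sigma / mu)**2
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import coarse_grain, sample_entropy

__all__ = [
    "RE_VARIANTS",
    "ParamGrid",
    "ReSurface",
    "AcceptanceReport",
    "relative_error",
    "re_grid_over_csf",
    "acceptable_parameter_space",
]

RE_VARIANTS: dict[str, Callable[[float, float], float]] = {
    "literal": lambda mu, sigma: 1.96 * sigma / mu**2,
    "ratio": lambda mu, sigma: 1.96 * sigma / mu,
    "squared": lambda mu, sigma: (1.96 * sigma / mu) ** 2,
}


def _default_r_values() -> tuple[float, ...]:
    return tuple(round(0.05 * k, 2) for k in range(1, 17))  # 0.05 .. 0.80


@dataclass(frozen=True)
class ParamGrid:
    """Grid of pattern lengths, tolerances, and scale factors to screen.

    Defaults give the 48-combination grid: m in {1, 2, 3} and r from 0.05
    to 0.80 in steps of 0.05, evaluated over scale factors 1..10.
    """

    m_values: tuple[int, ...] = (1, 2, 3)
    r_values: tuple[float, ...] = field(default_factory=_default_r_values)
    scales: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if not (self.m_values and self.r_values and self.scales):
            raise ValueError("grid axes must be non-empty")

    @property
    def n_combinations(self) -> int:
        return len(self.m_values) * len(self.r_values)


@dataclass
class ReSurface:
    """Median-across-subjects relative error per (m, r, scale) cell.

    ``table`` columns: m, r, scale, median_re (NaN where failed), failed,
    n_failed_subjects.  ``variant`` names the formula used.
    """

    table: pd.DataFrame
    threshold: float = 0.1
    variant: str = "literal"
    n_subjects: int = 0


@dataclass
class AcceptanceReport:
    """Acceptable (m, r) combinations and the per-m best combination."""

    acceptable: list[tuple[int, float]]
    per_m_best: pd.DataFrame
    threshold: float
    variant: str


def relative_error(sampens: Sequence[float], variant: str = "literal") -> float:
    """Relative error of a set of SampEn estimates.

    Applies the configured formula to the mean and standard deviation of
    the inputs.  Any NaN among the inputs marks the cell as failed and
    NaN is returned (no relative error exists for the cell); a
    non-positive mean is a usage error.
    """
    if variant not in RE_VARIANTS:
        raise ValueError(f"unknown RE variant {variant!r}; choose from {sorted(RE_VARIANTS)}")
    values = np.asarray(list(sampens), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 SampEn values")
    if np.isnan(values).any():
        return float("nan")
    mu = float(values.mean())
    sigma = float(values.std())
    if mu <= 0:
        raise ValueError(f"mean SampEn must be positive, got {mu}")
    return float(RE_VARIANTS[variant](mu, sigma))


def re_grid_over_csf(
    csf: Sequence[np.ndarray] | Mapping[int, np.ndarray],
    grid: ParamGrid | None = None,
    variant: str = "literal",
    threshold: float = 0.1,
) -> ReSurface:
    """Median relative-error surface over a grid, from per-subject CSF signals.

    ``csf`` maps each subject to an (n_csf_signals x time) matrix.  Per
    subject and (m, r, scale): SampEn of every CSF signal's coarse-grained
    series (scale-invariant tolerance anchored at each signal's scale-1
    SD), then the relative error across that subject's signals.  The
    surface value is the median across subjects; a cell is failed when
    any subject has a failed SampEn there.
    """
    if grid is None:
        grid = ParamGrid()
    matrices = list(csf.values()) if isinstance(csf, Mapping) else list(csf)
    if not matrices:
        raise ValueError("no CSF subjects provided")
    for mat in matrices:
        if np.atleast_2d(mat).shape[0] < 2:
            raise ValueError("each subject needs >= 2 CSF signals for a relative error")

    n_cells = len(grid.m_values) * len(grid.r_values) * len(grid.scales)
    re_per_subject = np.full((len(matrices), n_cells), np.nan)
    failed_any = np.zeros(n_cells, dtype=bool)
    n_failed_subjects = np.zeros(n_cells, dtype=int)

    for si, mat in enumerate(matrices):
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        sds = mat.std(axis=1)
        # coarse-grain once per (signal, scale); SampEn per (m, r) on top
        coarse = {
            l: [coarse_grain(sig, l) for sig in mat] for l in grid.scales
        }
        cell = 0
        for m in grid.m_values:
            for r in grid.r_values:
                for l in grid.scales:
                    sampens = [
                        sample_entropy(y, m, r, sd_ref=sd)
                        for y, sd in zip(coarse[l], sds)
                    ]
                    if any(math.isnan(v) for v in sampens):
                        failed_any[cell] = True
                        n_failed_subjects[cell] += 1
                    else:
                        re_per_subject[si, cell] = relative_error(sampens, variant)
                    cell += 1

    records = []
    cell = 0
    for m in grid.m_values:
        for r in grid.r_values:
            for l in grid.scales:
                if failed_any[cell]:
                    median_re = float("nan")
                else:
                    median_re = float(np.median(re_per_subject[:, cell]))
                records.append(
                    {
                        "m": m,
                        "r": r,
                        "scale": l,
                        "median_re": median_re,
                        "failed": bool(failed_any[cell]),
                        "n_failed_subjects": int(n_failed_subjects[cell]),
                    }
                )
                cell += 1
    table = pd.DataFrame.from_records(records)
    return ReSurface(
        table=table, threshold=threshold, variant=variant, n_subjects=len(matrices)
    )


def acceptable_parameter_space(surface: ReSurface) -> AcceptanceReport:
    """Acceptable (m, r) pairs and the per-m minimizer of the mean RE.

    A combination is acceptable when no (m, r, scale) cell failed and the
    mean relative error across scales is at or below the threshold.  The
    per-m report lists, for each pattern length, the failure-free (m, r)
    with the lowest mean RE across scales; an empty acceptable set is a
    valid result, not an error.
    """
    tab = surface.table
    grouped = tab.groupby(["m", "r"], sort=True).agg(
        mean_re=("median_re", "mean"),
        any_failed=("failed", "any"),
    )
    ok = grouped[~grouped["any_failed"]]
    acceptable = [
        (int(m), float(r))
        for (m, r), row in ok.iterrows()
        if row["mean_re"] <= surface.threshold
    ]
    best_rows = []
    for m, sub in ok.groupby(level="m"):
        idx = sub["mean_re"].idxmin()
        best_rows.append({"m": int(idx[0]), "r": float(idx[1]), "mean_re": float(sub.loc[idx, "mean_re"])})
    per_m_best = pd.DataFrame(best_rows, columns=["m", "r", "mean_re"])
    return AcceptanceReport(
        acceptable=acceptable,
        per_m_best=per_m_best,
        threshold=surface.threshold,
        variant=surface.variant,
    )
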