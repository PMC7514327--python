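"""Complexity mapping: nMSE, eMSE, edge-based nMSE and level aggregation.

Three complexity measures are tabulated per subject and scale factor:

* **nMSE** — multiscale entropy of each node's BOLD-like series
  (neuronal complexity);
* **eMSE** — multiscale entropy of each phase-coherence edge series
  (functional complexity);
* **edge-based nMSE** — a node's mean eMSE over its n-1 incident edges.

Node-level values aggregate to network level (unweighted mean over the
member nodes of a resting-state network) and to whole-brain level
(unweighted mean over all nodes, or all edges for eMSE).  All means skip
failed cells and record how many were skipped; a unit whose members all
failed is itself a failed cell.  Everything lives in one tidy table
keyed by (measure, level, unit, subject, scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RsnAtlas
from .entropy import EntropyParams, mse_profile
from .phase import EdgeSeriesSet

__all__ = [
    "TABLE_COLUMNS",
    "DivergenceMap",
    "PairedTestResult",
    "ScaleSummary",
    "node_mse_table",
    "edge_mse_table",
    "edge_based_node_mse",
    "network_mse",
    "whole_brain_mse",
    "mean_over_scales",
    "divergence_map",
    "paired_level_test",
]

TABLE_COLUMNS = ["measure", "level", "unit", "subject", "scale", "value", "failed"]


@dataclass
class DivergenceMap:
    """Per-edge group-mean SampEn difference: high scale minus reference.

    Positive values mean entropy increases with scale.  Edges failed at
    either scale for any subject are excluded and listed.
    """

    table: pd.DataFrame  # columns: unit, divergence
    excluded: list[str]
    reference_scale: int
    high_scale: int

    def fraction_positive(self) -> float:
        if len(self.table) == 0:
            return float("nan")
        return float((self.table["divergence"] > 0).mean())


@dataclass
class PairedTestResult:
    """Two-tailed paired t-test report."""

    t: float
    df: int
    p: float


@dataclass
class ScaleSummary:
    """Mean-over-scales summaries.

    ``per_subject``: one row per (measure, level, unit, subject) with the
    mean over non-failed requested scales (``n_skipped`` counts failed
    scales; the cell is failed when all were).  ``across_subjects``: per
    unit median and quartiles of the per-subject means, for box-style
    reporting.
    """

    per_subject: pd.DataFrame
    across_subjects: pd.DataFrame
    scales: tuple[int, ...]


def _profiles_to_records(
    measure: str, level: str, unit: str, subject, profile
) -> list[dict]:
    return [
        {
            "measure": measure,
            "level": level,
            "unit": unit,
            "subject": subject,
            "scale": int(l),
            "value": float(v),
            "failed": bool(f),
        }
        for l, v, f in zip(profile.params.scales, profile.values, profile.failed)
    ]


def node_mse_table(
    signals: Mapping[object, np.ndarray], params: EntropyParams
) -> pd.DataFrame:
    """nMSE: one multiscale-entropy profile per node per subject.

    ``signals`` maps subject id to a preprocessed node x time matrix.
    """
    records: list[dict] = []
    for subject, mat in signals.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        for node in range(mat.shape[0]):
            prof = mse_profile(mat[node], params)
            records.extend(
                _profiles_to_records("nMSE", "node", str(node + 1), subject, prof)
            )
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


def edge_mse_table(
    edge_sets: Mapping[object, EdgeSeriesSet], params: EntropyParams
) -> pd.DataFrame:
    """eMSE: one multiscale-entropy profile per phase-coherence edge per subject."""
    records: list[dict] = []
    for subject, es in edge_sets.items():
        for k, (i, j) in enumerate(es.edge_index):
            prof = mse_profile(es.edge_values[k], params)
            records.extend(
                _profiles_to_records("eMSE", "edge", f"{i}-{j}", subject, prof)
            )
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


def _masked_mean(group: pd.DataFrame) -> pd.Series:
    ok = group.loc[~group["failed"], "value"]
    return pd.Series(
        {
            "value": float(ok.mean()) if len(ok) else float("nan"),
            "failed": bool(len(ok) == 0),
            "n_skipped": int(group["failed"].sum()),
        }
    )


def edge_based_node_mse(
    emse: pd.DataFrame, edge_index: Sequence[tuple[int, int]]
) -> pd.DataFrame:
    """Edge-based nMSE: per node, the mean eMSE of its incident edges.

    Failed incident cells are skipped (count recorded); a node whose
    incident edges all failed at a scale is failed there.
    """
    edges = emse[(emse["measure"] == "eMSE") & (emse["level"] == "edge")].copy()
    if edges.empty:
        raise ValueError("no eMSE edge records found")
    valid_units = {f"{i}-{j}" for i, j in edge_index}
    unknown = set(edges["unit"]) - valid_units
    if unknown:
        raise ValueError(f"edge units not in the canonical index: {sorted(unknown)[:5]}")
    ij = edges["unit"].str.split("-", expand=True).astype(int)
    long = pd.concat(
        [edges.assign(node=ij[0]), edges.assign(node=ij[1])], ignore_index=True
    )
    agg = (
        long.groupby(["node", "subject", "scale"], sort=True)
        .apply(_masked_mean, include_groups=False)
        .reset_index()
    )
    agg["measure"] = "edge_based_nMSE"
    agg["level"] = "node"
    agg["unit"] = agg["node"].astype(str)
    return agg[TABLE_COLUMNS + ["n_skipped"]]


def network_mse(table: pd.DataFrame, atlas: RsnAtlas) -> pd.DataFrame:
    """Network-level complexity: unweighted mean over each RSN's member nodes."""
    nodes = table[table["level"] == "node"].copy()
    if nodes.empty:
        raise ValueError("no node-level records found")
    node_ids = nodes["unit"].astype(int)
    unmapped = set(node_ids) - set(atlas.membership)
    if unmapped:
        raise ValueError(f"nodes without a network in the atlas: {sorted(unmapped)}")
    nodes["network"] = node_ids.map(atlas.membership)
    out_frames = []
    for measure, sub in nodes.groupby("measure", sort=True):
        agg = (
            sub.groupby(["network", "subject", "scale"], sort=True)
            .apply(_masked_mean, include_groups=False)
            .reset_index()
        )
        agg["measure"] = measure
        agg["level"] = "network"
        agg["unit"] = agg["network"]
        out_frames.append(agg[TABLE_COLUMNS + ["n_skipped"]])
    return pd.concat(out_frames, ignore_index=True)


def whole_brain_mse(table: pd.DataFrame) -> pd.DataFrame:
    """Whole-brain complexity: mean over all nodes (nMSE, edge-based nMSE)
    or all edges (eMSE), per subject per scale."""
    base = table[table["level"].isin(["node", "edge"])].copy()
    if base.empty:
        raise ValueError("no node- or edge-level records found")
    out_frames = []
    for measure, sub in base.groupby("measure", sort=True):
        agg = (
            sub.groupby(["subject", "scale"], sort=True)
            .apply(_masked_mean, include_groups=False)
            .reset_index()
        )
        agg["measure"] = measure
        agg["level"] = "whole_brain"
        agg["unit"] = "whole_brain"
        out_frames.append(agg[TABLE_COLUMNS + ["n_skipped"]])
    return pd.concat(out_frames, ignore_index=True)


def mean_over_scales(table: pd.DataFrame, scales: Sequence[int]) -> ScaleSummary:
    """Per-unit, per-subject mean over the requested scales.

    Skips failed scales (cell failed when all requested scales failed)
    and additionally reports the across-subject median and quartiles per
    unit, computed over non-failed summary cells.
    """
    scales = tuple(int(s) for s in scales)
    sub = table[table["scale"].isin(scales)]
    missing = set(scales) - set(sub["scale"].unique())
    if missing:
        raise ValueError(f"requested scales absent from the table: {sorted(missing)}")
    per_subject = (
        sub.groupby(["measure", "level", "unit", "subject"], sort=True)
        .apply(_masked_mean, include_groups=False)
        .reset_index()
    )
    ok = per_subject[~per_subject["failed"]]
    across = (
        ok.groupby(["measure", "level", "unit"], sort=True)["value"]
        .agg(
            median="median",
            q25=lambda v: float(np.quantile(v, 0.25)),
            q75=lambda v: float(np.quantile(v, 0.75)),
            n_subjects="count",
        )
        .reset_index()
    )
    return ScaleSummary(per_subject=per_subject, across_subjects=across, scales=scales)


def divergence_map(
    emse: pd.DataFrame, reference_scale: int = 2, high_scale: int = 10
) -> DivergenceMap:
    """Per-edge divergence: group-mean SampEn(high) - group-mean SampEn(reference).

    An edge failed at either scale for any subject is excluded from the
    map and reported in ``excluded``.
    """
    edges = emse[(emse["measure"] == "eMSE") & (emse["level"] == "edge")]
    both = edges[edges["scale"].isin([reference_scale, high_scale])]
    present = set(both["scale"].unique())
    if present != {reference_scale, high_scale}:
        raise ValueError(
            f"scales {reference_scale} and {high_scale} must both be present, found {sorted(present)}"
        )
    any_failed = both.groupby("unit")["failed"].any()
    excluded = sorted(any_failed[any_failed].index.tolist())
    ok = both[~both["unit"].isin(excluded)]
    means = ok.groupby(["unit", "scale"])["value"].mean().unstack("scale")
    div = (means[high_scale] - means[reference_scale]).rename("divergence")
    table = div.reset_index()
    return DivergenceMap(
        table=table,
        excluded=excluded,
        reference_scale=reference_scale,
        high_scale=high_scale,
    )


def paired_level_test(a: np.ndarray, b: np.ndarray) -> PairedTestResult:
    """Two-tailed paired t-test between two subject-paired value vectors.

    P-values are reported uncorrected.  Raises when the paired
    differences have zero variance (t undefined).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 paired values")
    d = a - b
    if np.std(d) <= 1e-12 * (1.0 + float(np.abs(d).max(initial=0.0))):
        raise ValueError("paired differences have zero variance; t undefined")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), df=a.size - 1, p=float(res.pvalue))
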