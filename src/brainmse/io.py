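"""File I/O: delimited matrices, tidy tables, atlas tables, cohort layout.

Matrix files are tab-delimited text.  The canonical orientation is
node x time: a header ``node<TAB>t1<TAB>...<TAB>tT`` followed by one row
per node (label, then values).  The transposed orientation (header
``time<TAB><node labels...>``, one row per time point) is detected from
the first header cell.  Values are written with 17 significant digits so
a read/write round trip is bit-exact for float64.

A cohort on disk is a directory with one matrix file per subject per
run, one CSF matrix per subject, a scores table, a truth table, an atlas
table, and a ``manifest.json`` tying them together.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import RsnAtlas
from .cohort import SyntheticCohort

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "write_tables",
    "write_atlas",
    "read_atlas",
    "write_cohort",
    "read_cohort",
]

_FLOAT_FMT = "%.17g"


class MatrixParseError(ValueError):
    """Raised when a delimited matrix file is malformed; names the line."""


def write_matrix(
    path: str | Path, matrix: np.ndarray, node_labels: list[str] | None = None
) -> Path:
    """Write a node x time matrix as tab-delimited text (canonical orientation)."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n_nodes, n_time = matrix.shape
    if node_labels is None:
        node_labels = [f"node{i:03d}" for i in range(1, n_nodes + 1)]
    if len(node_labels) != n_nodes:
        raise ValueError("one label per node required")
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(f"t{k}" for k in range(1, n_time + 1)) + "\n")
        for label, row in zip(node_labels, matrix):
            fh.write(label + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a delimited matrix file; returns (node x time matrix, node labels).

    Accepts the canonical node x time orientation and the transposed
    time x node orientation (auto-detected from the header).  Ragged rows
    and non-numeric cells raise :class:`MatrixParseError` with the line
    number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    transposed = header[0].strip().lower() == "time"
    labels = header[1:] if transposed else None
    n_cols = len(header)
    rows: list[list[float]] = []
    row_labels: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise MatrixParseError(
                f"{path}: line {lineno}: expected {n_cols} fields, got {len(parts)}"
            )
        row_labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise MatrixParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    matrix = np.asarray(rows, dtype=float)
    if transposed:
        return matrix.T, list(labels)
    return matrix, row_labels


def write_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write tidy result tables as <name>.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths.append(p)
    return paths


def write_atlas(path: str | Path, atlas: RsnAtlas) -> Path:
    df = pd.DataFrame(
        {
            "node": range(1, atlas.n_nodes + 1),
            "label": atlas.node_labels,
            "network": [atlas.membership[i] for i in range(1, atlas.n_nodes + 1)],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_atlas(path: str | Path) -> RsnAtlas:
    df = pd.read_csv(path, sep="\t")
    membership = dict(zip(df["node"].astype(int), df["network"]))
    # preserve first-appearance network order
    names = tuple(dict.fromkeys(df["network"]))
    return RsnAtlas(
        node_labels=tuple(df["label"]), membership=membership, network_names=names
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to disk; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    atlas = spec.resolved_atlas()
    labels = list(atlas.node_labels)
    subjects = []
    for s, runs in enumerate(cohort.node_signals, start=1):
        run_paths = []
        for r, run in enumerate(runs, start=1):
            p = outdir / f"sub-{s:03d}_run-{r}.tsv"
            write_matrix(p, run, labels)
            run_paths.append(p.name)
        csf_path = outdir / f"sub-{s:03d}_csf.tsv"
        write_matrix(
            csf_path,
            cohort.csf_signals[s - 1],
            [f"csf{k:02d}" for k in range(1, spec.n_csf_signals + 1)],
        )
        subjects.append({"id": s, "runs": run_paths, "csf": csf_path.name})
    scores = pd.DataFrame(
        {"subject": range(1, spec.n_subjects + 1), "score": cohort.scores}
    )
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    truth = {
        "planted_nodes": list(cohort.truth["planted_nodes"]),
        "score_weights": list(map(float, cohort.truth["score_weights"])),
        "score_noise_sd": float(cohort.truth["score_noise_sd"]),
        "lambdas": np.asarray(cohort.truth["lambdas"]).tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    write_atlas(outdir / "atlas.tsv", atlas)
    manifest = {
        "n_subjects": spec.n_subjects,
        "n_nodes": spec.n_nodes,
        "n_runs": spec.n_runs,
        "run_length": spec.run_length,
        "sampling_interval": spec.sampling_interval,
        "n_csf_signals": spec.n_csf_signals,
        "seed": spec.seed,
        "subjects": subjects,
        "scores": "scores.tsv",
        "atlas": "atlas.tsv",
        "truth": "truth.json",
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(
    manifest_path: str | Path,
) -> tuple[dict[int, list[np.ndarray]], dict[int, np.ndarray], pd.DataFrame, RsnAtlas]:
    """Load a cohort directory.

    Returns (run matrices per subject, CSF matrix per subject, scores
    table, atlas).  Missing referenced files raise FileNotFoundError.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    runs: dict[int, list[np.ndarray]] = {}
    csf: dict[int, np.ndarray] = {}
    n_runs = None
    for entry in manifest["subjects"]:
        sid = int(entry["id"])
        mats = []
        for rel in entry["runs"]:
            p = root / rel
            if not p.exists():
                raise FileNotFoundError(f"run file missing: {p}")
            mats.append(read_matrix(p)[0])
        if n_runs is None:
            n_runs = len(mats)
        elif len(mats) != n_runs:
            raise ValueError(f"subject {sid}: run count differs from the rest")
        runs[sid] = mats
        csf_p = root / entry["csf"]
        if not csf_p.exists():
            raise FileNotFoundError(f"CSF file missing: {csf_p}")
        csf[sid] = read_matrix(csf_p)[0]
    scores = pd.read_csv(root / manifest["scores"], sep="\t", float_precision="round_trip")
    atlas = read_atlas(root / manifest["atlas"])
    return runs, csf, scores, atlas
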