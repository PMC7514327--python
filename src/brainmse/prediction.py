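"""Behavioral prediction from complexity features.

Pipeline: assemble a subject x (unit, scale) feature matrix from one
complexity measure, rank features by the p-value of their Pearson
correlation with the behavioral score (ascending, no multiple-comparison
correction), keep the first ``n``, and run leave-one-subject-out (LOSO)
linear-kernel support vector regression.  Ranking and standardization
happen inside each fold on the training subjects only, so the held-out
score never leaks into its own fold.  Significance of the final
predicted-vs-actual correlation comes from a permutation test that
re-runs the whole LOSO pipeline on permuted scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

__all__ = [
    "PredictionResult",
    "PermutationResult",
    "assemble_features",
    "rank_features_by_correlation",
    "loso_svr_predict",
    "permutation_test",
]


@dataclass
class PredictionResult:
    """LOSO prediction outcome.

    One fold (and one trained model) per subject; ``selected`` holds each
    fold's ranked feature ids and ``common_features`` their intersection
    across folds.  ``r`` is the Pearson correlation between predicted and
    actual scores over all subjects.
    """

    subjects: list
    predictions: np.ndarray
    actual: np.ndarray
    selected: list[list[str]]
    common_features: list[str]
    r: float
    n_features: int


@dataclass
class PermutationResult:
    """Permutation significance of the LOSO correlation.

    ``p_value`` uses the add-one estimator
    ``(1 + #{permuted r >= observed r}) / (1 + B)`` and is therefore never
    exactly zero.
    """

    observed_r: float
    permuted_r: np.ndarray
    n_permutations: int
    p_value: float
    seed: int


def assemble_features(
    table: pd.DataFrame, measure: str, scales: Sequence[int]
) -> tuple[pd.DataFrame, list[str]]:
    """Subject x feature matrix for one measure over the given scales.

    Features are ordered unit-major, scale-minor with ids ``unit@s{scale}``.
    Features failed for any subject are dropped cohort-wide and returned
    in the dropped list.  A subject missing a requested unit/scale cell is
    an error.
    """
    level = "edge" if measure == "eMSE" else "node"
    scales = [int(s) for s in scales]
    sub = table[
        (table["measure"] == measure)
        & (table["level"] == level)
        & (table["scale"].isin(scales))
    ]
    if sub.empty:
        raise ValueError(f"no records for measure {measure!r} at scales {scales}")

    def unit_key(u: str):
        return tuple(int(p) for p in u.split("-"))

    units = sorted(sub["unit"].unique(), key=unit_key)
    wide_val = sub.pivot(index="subject", columns=["unit", "scale"], values="value")
    wide_fail = sub.pivot(index="subject", columns=["unit", "scale"], values="failed")
    expected = pd.MultiIndex.from_tuples(
        [(u, l) for u in units for l in scales], names=["unit", "scale"]
    )
    missing = expected.difference(wide_val.columns)
    if len(missing):
        raise ValueError(f"subjects missing cells for units/scales: {list(missing)[:5]}")
    wide_val = wide_val.reindex(columns=expected)
    wide_fail = wide_fail.reindex(columns=expected)
    absent = wide_fail.isna()
    if absent.values.any():
        where = [
            (subj, u, l)
            for (u, l) in wide_fail.columns[absent.any(axis=0)]
            for subj in wide_fail.index[absent[(u, l)]]
        ]
        raise ValueError(f"subjects missing unit/scale cells: {where[:5]}")
    wide_fail = wide_fail.astype(bool)
    drop_mask = wide_fail.any(axis=0) | wide_val.isna().any(axis=0)
    dropped = [f"{u}@s{l}" for (u, l), bad in drop_mask.items() if bad]
    kept = expected[~drop_mask.values]
    X = wide_val.loc[:, kept]
    X.columns = [f"{u}@s{l}" for u, l in kept]
    return X, dropped


def _pearson_r_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of each column of X against y.

    Zero-variance columns get r = 0 and p = +inf (worst possible rank).
    """
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = sx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(np.where(zero_var, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p = np.where(zero_var, np.inf, p)
    return r, p


def rank_features_by_correlation(
    features: pd.DataFrame | np.ndarray, scores: np.ndarray, n: int
) -> list[str]:
    """First ``n`` feature ids sorted by ascending correlation p-value.

    Ties are broken by |r| descending, then by column position; no
    multiple-comparison correction is applied.  Zero-variance columns
    rank last.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [str(i) for i in range(X.shape[1])]
    y = np.asarray(scores, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 subjects to rank features")
    if X.shape[0] != y.size:
        raise ValueError("feature rows and score length differ")
    r, p = _pearson_r_p(X, y)
    order = np.lexsort((np.arange(len(names)), -np.abs(r), p))
    return [names[k] for k in order[: min(n, len(names))]]


def _fit_predict_fold(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> float:
    """Standardize with training statistics, fit linear SVR, predict one subject."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    model = SVR(kernel="linear")
    model.fit((X_train - mu) / sd, y_train)
    return float(model.predict(((X_test - mu) / sd).reshape(1, -1))[0])


def loso_svr_predict(
    features: pd.DataFrame, scores: np.ndarray, n: int
) -> PredictionResult:
    """Leave-one-subject-out linear-kernel SVR prediction.

    For each held-out subject, features are ranked on the training
    subjects only, the first ``n`` selected, a linear-kernel SVR (library
    defaults: C = 1, epsilon = 0.1) trained on training-standardized
    columns, and the held-out score predicted.  The result carries the
    per-fold selections, their cross-fold intersection, and the Pearson
    correlation between predictions and actual scores.
    """
    y = np.asarray(scores, dtype=float).ravel()
    if features.shape[0] != y.size:
        raise ValueError("feature rows and score length differ")
    if y.size < 10:
        raise ValueError(f"need at least 10 subjects for LOSO, got {y.size}")
    if np.std(y) == 0:
        raise ValueError("scores are constant; prediction correlation undefined")
    subjects = list(features.index)
    names = list(features.columns)
    col_pos = {c: k for k, c in enumerate(names)}
    X = features.to_numpy(dtype=float)
    predictions = np.empty(y.size)
    selected: list[list[str]] = []
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        sel = rank_features_by_correlation(features[mask], y[mask], n)
        cols = [col_pos[c] for c in sel]
        predictions[i] = _fit_predict_fold(X[mask][:, cols], y[mask], X[i, cols])
        selected.append(sel)
    common = set(selected[0])
    for s in selected[1:]:
        common &= set(s)
    r = float(stats.pearsonr(predictions, y).statistic)
    return PredictionResult(
        subjects=subjects,
        predictions=predictions,
        actual=y,
        selected=selected,
        common_features=sorted(common, key=lambda c: col_pos[c]),
        r=r,
        n_features=min(n, len(names)),
    )


def permutation_test(
    features: pd.DataFrame,
    scores: np.ndarray,
    n: int,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation significance of the LOSO prediction correlation.

    Keeps feature selection and SVR training identical while permuting
    the score vector ``n_permutations`` times and re-running the full
    LOSO pipeline for each.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations for a meaningful p-value")
    observed = loso_svr_predict(features, scores, n).r
    rng = np.random.default_rng(seed)
    y = np.asarray(scores, dtype=float).ravel()
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted[b] = loso_svr_predict(features, rng.permutation(y), n).r
    exceed = int(np.sum(permuted >= observed))
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationResult(
        observed_r=observed,
        permuted_r=permuted,
        n_permutations=n_permutations,
        p_value=float(p),
        seed=seed,
    )
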