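"""Minimum-Redundancy-Maximum-Relevance (mRMR) feature selection.

Greedy forward selection under the MID (mutual-information difference)
criterion: the first feature maximizes relevance I(f; class); each subsequent
feature maximizes I(f; class) - (1/|S|) * sum_{s in S} I(f; s) over the
already-selected set S.  Continuous features are discretized into
equal-frequency bins (default 10) before the plug-in MI estimate.  All ties
break lexicographically by feature name, so rankings are deterministic across
platforms.  The selected-feature count k is constrained to {10, 15, 20} and
tuned by cross-validated accuracy, ties resolved toward the smaller k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .features import feature_columns

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATE_K = (10, 15, 20)
DEFAULT_N_BINS = 10


@dataclass
class SelectionResult:
    """Ranked features plus the cross-validated choice of k."""

    ranked_features: list[str]
    relevance: dict[str, float]            # MI with the class label, nats
    chosen_k: int
    per_k_cv_accuracy: dict[int, float] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return self.ranked_features[: self.chosen_k]


def discretize(values: Sequence[float] | np.ndarray,
               n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-frequency integer bin labels.

    Bin of the value with (stable) rank r among n values is
    ``r * n_bins // n``; ties are broken by original order, so a constant
    column collapses to a single bin only when all values are equal.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D column")
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot discretize non-finite values")
    if int(n_bins) < 2:
        raise ValueError("n_bins must be >= 2")
    n = v.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if v.min() == v.max():
        return np.zeros(n, dtype=np.int64)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return ranks * int(n_bins) // n


def bin_edges(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Upper bounds of the equal-frequency bins fitted on ``values``.

    Lets bins be frozen on a training split and applied to held-out data with
    :func:`apply_bins` (no information leakage during tuning).
    """
    v = np.sort(np.asarray(values, dtype=float))
    labels = discretize(v, n_bins)
    uppers = [v[labels <= b].max() for b in range(labels.max() + 1)]
    return np.asarray(uppers[:-1])   # last bin is open-ended


def apply_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, np.asarray(values, dtype=float),
                           side="left").astype(np.int64)


def mutual_information(a: Sequence[int] | np.ndarray,
                       b: Sequence[int] | np.ndarray) -> float:
    """Plug-in MI estimate in nats between two discrete label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("label vectors must be non-empty")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb)
    return _mi_from_counts(joint)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    pij = joint / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = pij * np.log(pij / (pi * pj))
    return float(np.nansum(term))


def _pair_mi(codes_a: np.ndarray, codes_b: np.ndarray,
             na: int, nb: int) -> float:
    joint = np.bincount(codes_a * nb + codes_b,
                        minlength=na * nb).reshape(na, nb)
    return _mi_from_counts(joint)


def _batch_pair_mi(codes2d: np.ndarray, codes_b: np.ndarray,
                   na: int, nb: int) -> np.ndarray:
    """MI of every row of ``codes2d`` (F, n) with ``codes_b``, in one pass.

    Joint contingency tables for all F features come from a single bincount
    over offset-combined codes; the plug-in formula is then vectorized.
    """
    F, n = codes2d.shape
    flat = (codes2d * nb + codes_b[None, :]
            + (np.arange(F, dtype=np.int64) * (na * nb))[:, None])
    counts = np.bincount(flat.ravel(), minlength=F * na * nb) \
        .reshape(F, na, nb)
    pij = counts / n
    pi = pij.sum(axis=2, keepdims=True)
    pj = pij.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = pij * np.log(pij / (pi * pj))
    return np.nansum(term, axis=(1, 2))


def mrmr_rank(
    table: pd.DataFrame,
    max_k: int,
    n_bins: int = DEFAULT_N_BINS,
    label_column: str = "label",
) -> SelectionResult:
    """Greedy MID ranking of a feature table's columns against its label.

    Returns a SelectionResult whose ``ranked_features`` holds the top
    ``max_k`` features in selection order (so any smaller top-k is a prefix);
    ``chosen_k`` defaults to ``max_k`` until :func:`tune_k` refines it.
    """
    feats = feature_columns(table)
    y = table[label_column].to_numpy()
    if len(pd.unique(y)) < 2:
        raise ValueError("mRMR ranking requires >= 2 classes in the table")
    if max_k > len(feats):
        raise ValueError(f"max_k={max_k} exceeds feature count {len(feats)}")

    names = sorted(feats)               # lexicographic tie-break base order
    codes2d = np.stack([discretize(table[f].to_numpy(), n_bins)
                        for f in names]).astype(np.int64)
    ncat = int(codes2d.max()) + 1
    _, yi = np.unique(y, return_inverse=True)
    ny = int(yi.max()) + 1

    rel = _batch_pair_mi(codes2d, yi.astype(np.int64), ncat, ny)
    relevance = {f: float(r) for f, r in zip(names, rel)}

    selected: list[str] = []
    remaining = np.ones(len(names), dtype=bool)
    redundancy_sum = np.zeros(len(names))
    tol = 1e-12                         # float noise from summation order
    while len(selected) < max_k:
        if selected:
            scores = rel - redundancy_sum / len(selected)
        else:
            scores = rel
        masked = np.where(remaining, scores, -np.inf)
        # first index within tolerance of the maximum = lexicographic winner
        best = int(np.flatnonzero(masked >= masked.max() - tol)[0])
        selected.append(names[best])
        remaining[best] = False
        redundancy_sum += _batch_pair_mi(codes2d, codes2d[best], ncat, ncat)
    return SelectionResult(ranked_features=selected, relevance=relevance,
                           chosen_k=max_k)


def tune_k(
    table: pd.DataFrame,
    candidates: Iterable[int],
    trainer: Callable[[pd.DataFrame, list[str]], Callable[[pd.DataFrame], np.ndarray]],
    cv: Sequence[tuple[np.ndarray, np.ndarray]],
    n_bins: int = DEFAULT_N_BINS,
) -> SelectionResult:
    """Choose k among the candidates by cross-validated accuracy.

    ``trainer(train_table, features)`` must return a predictor mapping a table
    to predicted labels.  Ranking is refit on each fold's training split, so
    no held-out information reaches the selection.  Ties go to the smaller k.
    The returned ranking is refit on the full table.
    """
    cands = sorted({int(k) for k in candidates})
    feats = feature_columns(table)
    usable = [k for k in cands if k <= len(feats)]
    for k in cands:
        if k not in usable:
            logger.warning("candidate k=%d exceeds feature count %d; skipped",
                           k, len(feats))
    if not usable:
        raise ValueError("no usable candidate k")
    max_k = max(usable)

    hits = {k: 0 for k in usable}
    total = 0
    for train_idx, test_idx in cv:
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        ranking = mrmr_rank(train, max_k, n_bins=n_bins)
        truth = test["label"].to_numpy()
        total += len(test)
        for k in usable:
            top = ranking.ranked_features[:k]
            predict = trainer(train, top)
            pred = np.asarray(predict(test))
            hits[k] += int((pred == truth).sum())
    per_k = {k: hits[k] / total for k in usable}
    chosen = min(usable, key=lambda k: (-per_k[k], k))

    final = mrmr_rank(table, max_k, n_bins=n_bins)
    final.chosen_k = chosen
    final.per_k_cv_accuracy = per_k
    return final
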