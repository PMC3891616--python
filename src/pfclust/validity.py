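"""Evaluation of clusterings against ground truth.

Covers the three layers used to score tissue segmentations:

* cluster-to-class matching and overall clustering accuracy (the Huang
  index ``h = sum_i c_i / n``),
* per-class binary confusion counts with sensitivity, specificity and
  classification accuracy,
* prototype quality as the permutation-minimized squared Frobenius
  distance to a set of ideal centroids.

Cluster labels are arbitrary, so every score here is invariant to
relabeling; matching is done by optimal assignment on the contingency
table rather than greedily.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations
from typing import Dict, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "match_clusters",
    "huang_accuracy",
    "confusion",
    "se_sp_ca",
    "centroid_error",
    "evaluate_labels",
]

#: True labels below zero mark unlabeled objects (e.g. injected
#: outliers); they are excluded from matching and every score.
UNLABELED = -1


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts over a predicted vs. true mask."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class EvaluationReport:
    """Bundle of per-class and overall clustering scores."""

    matching: Dict[int, int]
    huang_h: float
    per_class: Dict[int, Dict[str, float]]
    centroid_error: Optional[float] = None


def _check_labels(pred, true):
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError(
            f"label vectors differ in length: {pred.size} vs {true.size}"
        )
    if pred.size == 0:
        raise ValueError("empty label vectors")
    keep = true >= 0
    if not keep.any():
        raise ValueError("no labeled objects to evaluate")
    return pred[keep], true[keep]


def _contingency(pred: np.ndarray, true: np.ndarray):
    pred_ids = np.unique(pred)
    true_ids = np.unique(true)
    table = np.zeros((pred_ids.size, true_ids.size), dtype=np.int64)
    pi = np.searchsorted(pred_ids, pred)
    ti = np.searchsorted(true_ids, true)
    np.add.at(table, (pi, ti), 1)
    return pred_ids, true_ids, table


def match_clusters(pred_labels, true_labels) -> Dict[int, int]:
    """One-to-one cluster-to-class assignment maximizing total overlap.

    Solved as an optimal (Hungarian) assignment on the contingency
    table, so the result is deterministic and independent of label
    order; among equally good assignments the lowest index pair wins.
    When cluster and class counts differ, the surplus side is left
    unmatched.

    Returns
    -------
    dict
        Mapping predicted cluster id -> matched true class id.
    """
    pred, true = _check_labels(pred_labels, true_labels)
    pred_ids, true_ids, table = _contingency(pred, true)
    # maximize overlap == minimize negated table; the tiny index-based
    # tie-break keeps equal-overlap assignments deterministic
    eps = 1.0 / (4.0 * table.size + 4)
    cost = -table.astype(np.float64)
    cost += eps * (np.arange(table.shape[0])[:, None] + np.arange(table.shape[1])) / (
        table.shape[0] + table.shape[1]
    )
    rows, cols = linear_sum_assignment(cost)
    return {int(pred_ids[r]): int(true_ids[c]) for r, c in zip(rows, cols)}


def huang_accuracy(pred_labels, true_labels) -> float:
    """Clustering accuracy ``h = (sum_i c_i) / n``.

    ``c_i`` is the overlap between cluster i and its optimally matched
    true class; unmatched clusters contribute nothing. Equals 1 exactly
    for a perfect (relabeled) clustering.
    """
    pred, true = _check_labels(pred_labels, true_labels)
    matching = match_clusters(pred, true)
    correct = sum(
        int(np.sum((pred == k) & (true == c))) for k, c in matching.items()
    )
    return correct / pred.size


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Binary confusion counts between two boolean maps of equal shape."""
    pred = np.asarray(pred_mask).astype(bool)
    true = np.asarray(true_mask).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def se_sp_ca(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and classification accuracy.

    ``Se = TP/(TP+FN)``, ``Sp = TN/(TN+FP)``,
    ``CA = (TP+TN)/(TP+FN+TN+FP)``. An undefined ratio (empty positive
    or negative ground truth) raises rather than silently returning 0.
    """
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive ground truth")
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative ground truth")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    ca = (c.tp + c.tn) / c.total
    return se, sp, ca


def centroid_error(V, V_ideal) -> float:
    """Squared Frobenius distance to ideal centroids, minimized over
    row permutations of ``V``.

    The permutation minimization makes the score invariant to cluster
    numbering; it is solved as an assignment problem on the pairwise
    squared-distance matrix between rows.
    """
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))
    W = np.atleast_2d(np.asarray(V_ideal, dtype=np.float64))
    if V.shape != W.shape:
        raise ValueError(f"prototype shape mismatch: {V.shape} vs {W.shape}")
    diff = W[:, None, :] - V[None, :, :]
    cost = np.einsum("ijq,ijq->ij", diff, diff)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def evaluate_labels(
    pred_labels,
    true_labels,
    V=None,
    V_ideal=None,
) -> EvaluationReport:
    """Full report: matching, Huang accuracy, per-class Se/Sp/CA.

    Each matched (cluster, class) pair is scored one-vs-rest on the
    labeled objects. If both ``V`` and ``V_ideal`` are given the
    prototype error is included.
    """
    pred, true = _check_labels(pred_labels, true_labels)
    matching = match_clusters(pred, true)
    per_class: Dict[int, Dict[str, float]] = {}
    for k, c in matching.items():
        counts = confusion(pred == k, true == c)
        se, sp, ca = se_sp_ca(counts)
        per_class[int(c)] = {
            "se": se,
            "sp": sp,
            "ca": ca,
            "tp": counts.tp,
            "tn": counts.tn,
            "fp": counts.fp,
            "fn": counts.fn,
        }
    err = None
    if V is not None and V_ideal is not None:
        err = centroid_error(V, V_ideal)
    return EvaluationReport(
        matching=matching,
        huang_h=huang_accuracy(pred_labels, true_labels),
        per_class=per_class,
        centroid_error=err,
    )


def _brute_force_matching(pred_labels, true_labels) -> Dict[int, int]:
    """Exhaustive-search matching; exponential, for cross-checks only."""
    pred, true = _check_labels(pred_labels, true_labels)
    pred_ids, true_ids, table = _contingency(pred, true)
    n_p, n_t = table.shape
    best, best_map = -1, {}
    if n_p <= n_t:
        for perm in permutations(range(n_t), n_p):
            score = sum(table[i, perm[i]] for i in range(n_p))
            if score > best:
                best = score
                best_map = {
                    int(pred_ids[i]): int(true_ids[perm[i]]) for i in range(n_p)
                }
    else:
        for perm in permutations(range(n_p), n_t):
            score = sum(table[perm[j], j] for j in range(n_t))
            if score > best:
                best = score
                best_map = {
                    int(pred_ids[perm[j]]): int(true_ids[j]) for j in range(n_t)
                }
    return best_map
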