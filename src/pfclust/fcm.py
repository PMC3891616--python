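"""Fuzzy c-means (Bezdek's alternating optimization).

Minimizes ``J_m(U, V) = sum_i sum_j u_ij^m d2_ij`` subject to
row-stochastic memberships, by alternating the closed-form membership
and prototype updates until the prototypes stop moving.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    SINGULARITY_EPS,
    ClusteringResult,
    DegenerateClusterError,
    HyperParams,
    as_feature_matrix,
    check_fuzzy_memberships,
    has_converged,
    init_prototypes,
    squared_distances,
)

__all__ = [
    "fcm_objective",
    "fcm_update_memberships",
    "fcm_update_prototypes",
    "run_fcm",
]


def fcm_objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    m: float,
    norm_matrix: Optional[np.ndarray] = None,
) -> float:
    """Weighted within-cluster scatter ``sum_ij u_ij^m d2_ij``."""
    U = check_fuzzy_memberships(U)
    D = squared_distances(X, V, norm_matrix)
    if U.shape != D.shape:
        raise ValueError(f"U shape {U.shape} does not match N x K = {D.shape}")
    return float(np.sum(U**m * D))


def fcm_update_memberships(
    X: np.ndarray,
    V: np.ndarray,
    m: float,
    norm_matrix: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Closed-form membership update given fixed prototypes.

    ``u_ij = 1 / sum_s (d2_ij / d2_is)^(1/(m-1))`` — each point splits
    its unit mass over clusters by relative inverse distance.

    A point coincident with one or more prototypes gets crisp membership
    1 in the coincident cluster of lowest index and 0 elsewhere (the
    continuity limit of the formula, which requires all distances
    positive).
    """
    if not m > 1:
        raise ValueError("fuzzifier m must be > 1")
    D = squared_distances(X, V, norm_matrix)
    row_min = np.min(D, axis=1, keepdims=True)
    singular_rows = row_min[:, 0] < SINGULARITY_EPS
    # normalizing by the row minimum keeps the largest ratio at 1, so the
    # negative power can underflow but never overflow for small m - 1
    # singular rows may still overflow here; they are overwritten below
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        W = (D / np.maximum(row_min, SINGULARITY_EPS)) ** (-1.0 / (m - 1.0))
        U = W / W.sum(axis=1, keepdims=True)
    if np.any(singular_rows):
        for i in np.flatnonzero(singular_rows):
            U[i] = 0.0
            U[i, int(np.argmax(D[i] < SINGULARITY_EPS))] = 1.0
    return U


def fcm_update_prototypes(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    """Prototype update: each center is the ``u^m``-weighted mean.

    Raises
    ------
    DegenerateClusterError
        If some cluster's total weight ``sum_i u_ij^m`` vanishes.
    """
    X = as_feature_matrix(X)
    U = np.asarray(U, dtype=np.float64)
    if U.shape[0] != X.shape[0]:
        raise ValueError("U and X disagree on the number of observations")
    W = U**m
    mass = W.sum(axis=0)
    if np.any(mass <= 0):
        dead = np.flatnonzero(mass <= 0).tolist()
        raise DegenerateClusterError(f"cluster(s) {dead} have zero membership mass")
    return (W.T @ X) / mass[:, None]


def run_fcm(
    X: np.ndarray,
    K: int,
    params: Optional[HyperParams] = None,
    *,
    n_init: int = 1,
    init_V: Optional[np.ndarray] = None,
    norm_matrix: Optional[np.ndarray] = None,
) -> ClusteringResult:
    """Run fuzzy c-means to convergence.

    Parameters
    ----------
    X : array-like, shape (N, q)
    K : int
        Number of clusters, ``1 <= K <= N``.
    params : HyperParams, optional
        Fuzzifier, tolerance, iteration cap and seed.
    n_init : int
        Number of seeded random restarts; the run with the lowest final
        objective is returned. Ignored when ``init_V`` is given.
    init_V : ndarray, shape (K, q), optional
        Explicit initial prototypes (overrides random initialization).
    norm_matrix : ndarray, optional
        Positive-definite inducing matrix for the distance.

    Returns
    -------
    ClusteringResult
        With row-stochastic ``U``, prototypes ``V`` and a non-increasing
        objective trace.
    """
    params = params or HyperParams()
    X = as_feature_matrix(X)
    if init_V is not None:
        starts = [np.asarray(init_V, dtype=np.float64)]
    else:
        rng = params.rng()
        starts = [init_prototypes(X, K, rng) for _ in range(max(1, n_init))]

    best: Optional[ClusteringResult] = None
    for V0 in starts:
        res = _fcm_single(X, V0, params, norm_matrix)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best


def _fcm_single(
    X: np.ndarray,
    V0: np.ndarray,
    params: HyperParams,
    norm_matrix: Optional[np.ndarray],
) -> ClusteringResult:
    V = V0.copy()
    trace = []
    converged = False
    n_iter = 0
    U = None
    for n_iter in range(1, params.max_iter + 1):
        U = fcm_update_memberships(X, V, params.m, norm_matrix)
        V_new = fcm_update_prototypes(X, U, params.m)
        trace.append(fcm_objective(X, U, V_new, params.m, norm_matrix))
        if has_converged(V, V_new, params.tol):
            V = V_new
            converged = True
            break
        V = V_new
    # memberships consistent with the final prototypes; refreshing them
    # can only lower J given V, so the trace stays non-increasing
    U = fcm_update_memberships(X, V, params.m, norm_matrix)
    trace.append(fcm_objective(X, U, V, params.m, norm_matrix))
    return ClusteringResult(
        V=V,
        U=U,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )
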