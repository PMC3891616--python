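"""Possibilistic c-means (Krishnapuram & Keller).

Relaxes the fuzzy row-sum constraint: each typicality ``t_ij`` measures
the absolute compatibility of point i with cluster j, so far-away
points (noise, outliers) get low typicality in *every* cluster instead
of being forced to split a unit mass. The price is that typicality
columns decouple — prototypes can collapse onto the same mode — and the
objective needs per-cluster scale parameters ``eta_j`` fixing where
typicality crosses one half.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .core import (
    ClusteringResult,
    CoincidentClustersWarning,
    DegenerateClusterError,
    HyperParams,
    as_feature_matrix,
    check_fuzzy_memberships,
    has_converged,
    squared_distances,
)
from .fcm import fcm_update_prototypes, run_fcm

__all__ = [
    "estimate_scales",
    "pcm_update_typicalities",
    "pcm_objective",
    "run_pcm",
]


def estimate_scales(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    m: float,
    multiplier: float = 1.0,
    method: str = "weighted_mean",
) -> np.ndarray:
    """Per-cluster scale parameters from a fuzzy partition.

    Two estimators, both usually computed once from a terminal FCM run
    and frozen:

    ``"weighted_mean"``
        The classical fuzzy-weighted mean squared distance,
        ``eta_j = multiplier * sum_i u_ij^m d2_ij / sum_i u_ij^m``.
        Faithful to the original possibilistic formulation, but every
        point contributes — gross outliers (which hold membership ~1/K
        in each cluster) can inflate it far beyond the within-cluster
        scatter.
    ``"core_median"``
        The median squared distance over the cluster's fuzzy core
        (points with ``u_ij > 0.5``), times ``multiplier``. Robust to
        outlier contamination — exactly the regime the possibilistic
        stage exists for — at the price of ignoring the membership
        weighting; falls back to the weighted mean for a cluster whose
        core is empty.

    Raises
    ------
    DegenerateClusterError
        If a cluster has no membership mass or a zero scale (all mass on
        points coincident with the center) — the possibilistic updates
        need strictly positive scales.
    """
    U = check_fuzzy_memberships(U)
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if method not in ("weighted_mean", "core_median"):
        raise ValueError(f"unknown scale estimator {method!r}")
    D = squared_distances(X, V)
    if U.shape != D.shape:
        raise ValueError(f"U shape {U.shape} does not match N x K = {D.shape}")
    W = U**m
    mass = W.sum(axis=0)
    if np.any(mass <= 0):
        raise DegenerateClusterError("cluster with zero membership mass")
    scales = (W * D).sum(axis=0) / mass
    if method == "core_median":
        for j in range(D.shape[1]):
            # guard must exceed the membership error left by a finitely
            # converged FCM run (~tol), so points ambivalent between
            # clusters (u = 0.5 up to convergence error) stay out
            core = U[:, j] > 0.5 + 1e-3
            if core.any():
                scales[j] = np.median(D[core, j])
    scales = multiplier * scales
    if np.any(scales <= 0):
        dead = np.flatnonzero(scales <= 0).tolist()
        raise DegenerateClusterError(
            f"cluster(s) {dead} have zero scale (all mass on coincident points)"
        )
    return scales


def pcm_update_typicalities(
    X: np.ndarray, V: np.ndarray, scales: np.ndarray, m: float
) -> np.ndarray:
    """Typicality update ``t_ij = (1 + d2_ij / eta_j)^(-1/(m-1))``.

    Entries lie in (0, 1]; ``t_ij = 1`` iff the point coincides with
    center j, and ``t_ij = 0.5`` exactly where ``d2_ij = eta_j``. Rows
    are not constrained to sum to one.
    """
    if not m > 1:
        raise ValueError("exponent m must be > 1")
    scales = np.asarray(scales, dtype=np.float64)
    if np.any(scales <= 0):
        raise ValueError("scales must be strictly positive")
    D = squared_distances(X, V)
    if scales.shape != (D.shape[1],):
        raise ValueError("scales must have one entry per cluster")
    return (1.0 + D / scales[None, :]) ** (-1.0 / (m - 1.0))


def pcm_objective(
    X: np.ndarray, T: np.ndarray, V: np.ndarray, scales: np.ndarray, m: float
) -> float:
    """``sum_ij t_ij^m d2_ij + sum_j eta_j sum_i (1 - t_ij)^m``."""
    T = np.asarray(T, dtype=np.float64)
    D = squared_distances(X, V)
    if T.shape != D.shape:
        raise ValueError(f"T shape {T.shape} does not match N x K = {D.shape}")
    scales = np.asarray(scales, dtype=np.float64)
    return float(np.sum(T**m * D) + np.sum(scales * np.sum((1.0 - T) ** m, axis=0)))


def run_pcm(
    X: np.ndarray,
    K: int,
    params: Optional[HyperParams] = None,
    *,
    init_U: Optional[np.ndarray] = None,
    init_V: Optional[np.ndarray] = None,
    fixed_scale: Optional[float] = None,
    scale_multiplier: float = 1.0,
    scale_method: str = "weighted_mean",
    n_init: int = 1,
) -> ClusteringResult:
    """Run possibilistic c-means to convergence.

    Unless ``init_U``/``init_V`` are supplied, an internal FCM run
    provides them (possibilistic iterations are notoriously sensitive to
    initialization; FCM seeding is the standard remedy). Scales are set
    once — estimated from the initial fuzzy partition via
    ``scale_method`` (see :func:`estimate_scales`), or all equal to
    ``fixed_scale`` if given — and frozen for the whole run.

    Emits :class:`CoincidentClustersWarning` when any two terminal
    prototypes lie within ``params.tol`` of each other.
    """
    params = params or HyperParams()
    X = as_feature_matrix(X)
    if (init_U is None) != (init_V is None):
        raise ValueError("provide both init_U and init_V, or neither")
    if init_U is None:
        seeded = run_fcm(X, K, params, n_init=n_init)
        init_U, init_V = seeded.U, seeded.V
    init_V = np.asarray(init_V, dtype=np.float64)

    if fixed_scale is not None:
        if fixed_scale <= 0:
            raise ValueError("fixed_scale must be positive")
        scales = np.full(init_V.shape[0], float(fixed_scale))
    else:
        scales = estimate_scales(
            X, init_U, init_V, params.m, scale_multiplier, scale_method
        )

    V = init_V.copy()
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        T = pcm_update_typicalities(X, V, scales, params.m)
        V_new = fcm_update_prototypes(X, T, params.m)  # same form as the FCM update
        trace.append(pcm_objective(X, T, V_new, scales, params.m))
        if has_converged(V, V_new, params.tol):
            V = V_new
            converged = True
            break
        V = V_new
    T = pcm_update_typicalities(X, V, scales, params.m)
    trace.append(pcm_objective(X, T, V, scales, params.m))

    warns = _coincidence_warnings(V, params.tol)
    return ClusteringResult(
        V=V,
        T=T,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        scales=scales,
        warnings=tuple(warns),
    )


def _coincidence_warnings(V: np.ndarray, tol: float) -> list:
    msgs = []
    K = V.shape[0]
    for j in range(K):
        for k in range(j + 1, K):
            if np.max(np.abs(V[j] - V[k])) < tol:
                msg = f"prototypes {j} and {k} are coincident (within tol={tol:g})"
                warnings.warn(msg, CoincidentClustersWarning, stacklevel=3)
                msgs.append(msg)
    return msgs
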