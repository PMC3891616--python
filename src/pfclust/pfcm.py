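"""Possibilistic fuzzy c-means (PFCM) and the hybrid FCM-then-PCM scheme.

PFCM (Pal et al.) optimizes one objective carrying both a fuzzy
membership matrix U (relative, row-stochastic) and a typicality matrix
T (absolute, unconstrained rows), blended by weights a and b:

    J = sum_ij (a u_ij^m + b t_ij^eta) d2_ij + sum_j gamma_j sum_i (1 - t_ij)^eta

The hybrid scheme (HPFCM) instead runs the two models in sequence: FCM
to convergence, whose terminal memberships both initialize and — via
the scale estimator — calibrate a possibilistic stage. The fuzzy stage
pins each prototype to a distinct cluster (avoiding the coincident-
cluster collapse a cold-started possibilistic run risks), and the
possibilistic stage then re-centers the prototypes robustly, letting
outliers fade to low typicality everywhere.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    ClusteringResult,
    DegenerateClusterError,
    HyperParams,
    as_feature_matrix,
    check_fuzzy_memberships,
    check_typicalities,
    has_converged,
    squared_distances,
)
from .fcm import fcm_update_memberships, run_fcm
from .pcm import estimate_scales, run_pcm

__all__ = [
    "pfcm_objective",
    "pfcm_update",
    "pfcm_update_prototypes",
    "run_pfcm",
    "run_hpfcm",
]


def pfcm_objective(
    X: np.ndarray,
    U: np.ndarray,
    T: np.ndarray,
    V: np.ndarray,
    params: HyperParams,
    gammas: np.ndarray,
) -> float:
    U = check_fuzzy_memberships(U)
    T = check_typicalities(T)
    D = squared_distances(X, V)
    if U.shape != D.shape or T.shape != D.shape:
        raise ValueError("U, T must both be N x K")
    gammas = np.asarray(gammas, dtype=np.float64)
    blend = params.a * U**params.m + params.b * T**params.eta
    penalty = np.sum(gammas * np.sum((1.0 - T) ** params.eta, axis=0))
    return float(np.sum(blend * D) + penalty)


def pfcm_update(
    X: np.ndarray, V: np.ndarray, params: HyperParams, gammas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled membership/typicality update given fixed prototypes.

    U follows exactly the FCM membership formula (the fuzzy subproblem
    is unchanged by the typicality term); T follows
    ``t_ij = 1 / (1 + ((b / gamma_j) d2_ij)^(1/(eta-1)))``.
    """
    gammas = np.asarray(gammas, dtype=np.float64)
    if np.any(gammas <= 0):
        raise ValueError("gammas must be strictly positive")
    U = fcm_update_memberships(X, V, params.m)
    D = squared_distances(X, V)
    T = 1.0 / (1.0 + ((params.b / gammas[None, :]) * D) ** (1.0 / (params.eta - 1.0)))
    return U, T


def pfcm_update_prototypes(
    X: np.ndarray, U: np.ndarray, T: np.ndarray, params: HyperParams
) -> np.ndarray:
    """Prototypes as ``(a u^m + b t^eta)``-weighted means of the data."""
    X = as_feature_matrix(X)
    U = np.asarray(U, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if U.shape != T.shape or U.shape[0] != X.shape[0]:
        raise ValueError("U and T must be N x K matrices matching X")
    W = params.a * U**params.m + params.b * T**params.eta
    mass = W.sum(axis=0)
    if np.any(mass <= 0):
        dead = np.flatnonzero(mass <= 0).tolist()
        raise DegenerateClusterError(f"cluster(s) {dead} have zero total weight")
    return (W.T @ X) / mass[:, None]


def run_pfcm(
    X: np.ndarray,
    K: int,
    params: Optional[HyperParams] = None,
    *,
    gammas: Optional[np.ndarray] = None,
    scale_multiplier: float = 1.0,
    scale_method: str = "weighted_mean",
    n_init: int = 1,
) -> ClusteringResult:
    """Run possibilistic fuzzy c-means to convergence.

    ``gamma_j`` defaults to the fuzzy-weighted mean squared distance of
    an internal terminal FCM run (the classical possibilistic scale
    estimator), computed once and frozen; the FCM run also provides
    the initial prototypes. With ``n_init > 1`` the whole pipeline is
    restarted and the run with the lowest final objective is kept.
    """
    params = params or HyperParams()
    X = as_feature_matrix(X)

    best: Optional[ClusteringResult] = None
    for restart in range(max(1, n_init)):
        sub = HyperParams(
            m=params.m,
            eta=params.eta,
            a=params.a,
            b=params.b,
            max_iter=params.max_iter,
            tol=params.tol,
            seed=None if params.seed is None else params.seed + restart,
        )
        seeded = run_fcm(X, K, sub)
        g = (
            np.asarray(gammas, dtype=np.float64)
            if gammas is not None
            else estimate_scales(
                X, seeded.U, seeded.V, sub.m, scale_multiplier, scale_method
            )
        )
        res = _pfcm_single(X, seeded.V, sub, g)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best


def _pfcm_single(
    X: np.ndarray, V0: np.ndarray, params: HyperParams, gammas: np.ndarray
) -> ClusteringResult:
    V = V0.copy()
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        U, T = pfcm_update(X, V, params, gammas)
        V_new = pfcm_update_prototypes(X, U, T, params)
        trace.append(pfcm_objective(X, U, T, V_new, params, gammas))
        if has_converged(V, V_new, params.tol):
            V = V_new
            converged = True
            break
        V = V_new
    U, T = pfcm_update(X, V, params, gammas)
    trace.append(pfcm_objective(X, U, T, V, params, gammas))
    return ClusteringResult(
        V=V,
        U=U,
        T=T,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        scales=np.asarray(gammas, dtype=np.float64),
    )


def run_hpfcm(
    X: np.ndarray,
    K: int,
    params: Optional[HyperParams] = None,
    *,
    fixed_scale: Optional[float] = None,
    scale_multiplier: float = 1.0,
    scale_method: str = "core_median",
    n_init: int = 1,
) -> ClusteringResult:
    """Hybrid scheme: FCM to convergence, then a possibilistic stage.

    Stage 1 runs FCM (``n_init`` restarts, best objective). Stage 2
    fixes the per-cluster scales — estimated from the terminal fuzzy
    partition, or all equal to ``fixed_scale`` when the scale is treated
    as a user parameter. Stage 3 iterates the possibilistic typicality
    and prototype updates starting from the FCM memberships and centers.

    The default scale estimator is the robust ``"core_median"`` (median
    squared distance over each cluster's fuzzy core): the hybrid's
    purpose is outlier robustness, and the classical fuzzy-weighted
    mean is itself inflated by the outliers the possibilistic stage is
    meant to reject, which drags the prototypes back toward the very
    solution the fuzzy stage would give under contamination. Pass
    ``scale_method="weighted_mean"`` for the classical calibration.

    Returns a result whose ``T``/``V`` are the terminal possibilistic
    matrix and prototypes, with the full stage-1 FCM result attached as
    ``result.stage1`` (its fuzzy matrix is also exposed as ``result.U``).
    """
    params = params or HyperParams()
    X = as_feature_matrix(X)
    stage1 = run_fcm(X, K, params, n_init=n_init)
    stage2 = run_pcm(
        X,
        K,
        params,
        init_U=stage1.U,
        init_V=stage1.V,
        fixed_scale=fixed_scale,
        scale_multiplier=scale_multiplier,
        scale_method=scale_method,
    )
    return ClusteringResult(
        V=stage2.V,
        U=stage1.U,
        T=stage2.T,
        objective_trace=stage2.objective_trace,
        n_iter=stage2.n_iter,
        converged=stage1.converged and stage2.converged,
        scales=stage2.scales,
        warnings=stage2.warnings,
        stage1=stage1,
    )
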