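"""Shared primitives for prototype-based fuzzy/possibilistic clustering.

All algorithms in this package alternate between a membership (or
typicality) update and a prototype update over an ``N x q`` feature
matrix.  This module holds what they share: hyper-parameter and result
containers, squared A-norm distances, seeded initialization, the
stopping rule, and the membership-matrix validators.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "HyperParams",
    "ClusteringResult",
    "DegenerateClusterError",
    "CoincidentClustersWarning",
    "as_feature_matrix",
    "squared_distances",
    "init_prototypes",
    "has_converged",
    "check_fuzzy_memberships",
    "check_typicalities",
]

#: Row sums of a fuzzy membership matrix must equal 1 within this.
FUZZY_ROW_SUM_TOL = 1e-9

#: Squared distances below this are treated as a coincident point/center.
SINGULARITY_EPS = 1e-12


class DegenerateClusterError(RuntimeError):
    """A cluster lost all of its membership mass (empty cluster)."""


class CoincidentClustersWarning(UserWarning):
    """Two or more terminal prototypes collapsed onto the same location.

    A known pathology of possibilistic c-means: typicality columns are
    decoupled, so nothing stops two prototypes from finding the same
    density mode.
    """


@dataclasses.dataclass(frozen=True)
class HyperParams:
    """Hyper-parameters shared by all four algorithms.

    Parameters
    ----------
    m : float
        Fuzzifier exponent for fuzzy memberships (and typicalities in
        plain possibilistic c-means). Must exceed 1; ``m -> 1`` gives
        hard assignments, larger values give softer partitions.
    eta : float
        Typicality exponent used by PFCM. Must exceed 1.
    a, b : float
        PFCM blending weights for the fuzzy and possibilistic terms.
        Both strictly positive (``b=0`` is accepted to recover FCM as a
        limiting case in the prototype update).
    max_iter : int
        Hard cap on alternating-optimization sweeps.
    tol : float
        Stop when the maximum absolute prototype change drops below this.
    seed : int or None
        Seeds prototype initialization; ``None`` means nondeterministic.
    """

    m: float = 2.0
    eta: float = 2.0
    a: float = 1.0
    b: float = 1.0
    max_iter: int = 300
    tol: float = 1e-5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.m > 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if not self.eta > 1:
            raise ValueError(f"typicality exponent eta must be > 1, got {self.eta}")
        if self.a < 0 or self.b < 0:
            raise ValueError("blending weights a, b must be nonnegative")
        if self.a == 0 and self.b == 0:
            raise ValueError("at least one of a, b must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if not self.tol > 0:
            raise ValueError("tol must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class ClusteringResult:
    """Terminal state of an alternating-optimization run.

    Attributes
    ----------
    U : ndarray or None
        ``N x K`` fuzzy membership matrix (row-stochastic). For the
        hybrid algorithm this is the stage-1 FCM matrix.
    T : ndarray or None
        ``N x K`` possibilistic typicality matrix (entries in (0, 1],
        no row constraint); present for PCM/PFCM/hybrid runs.
    V : ndarray
        ``K x q`` terminal prototypes.
    objective_trace : ndarray
        Objective value after each sweep of the (final) stage.
    n_iter : int
        Sweeps performed by the (final) stage.
    converged : bool
        Whether the prototype-change criterion was met before max_iter.
    scales : ndarray or None
        Per-cluster scale parameters (eta_j / gamma_j) where used.
    warnings : tuple of str
        Diagnostics raised during the run (e.g. coincident clusters).
    stage1 : ClusteringResult or None
        For the hybrid algorithm, the full stage-1 FCM result.
    """

    V: np.ndarray
    U: Optional[np.ndarray] = None
    T: Optional[np.ndarray] = None
    objective_trace: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )
    n_iter: int = 0
    converged: bool = False
    scales: Optional[np.ndarray] = None
    warnings: tuple = ()
    stage1: Optional["ClusteringResult"] = None

    @property
    def labels(self) -> np.ndarray:
        """Hard labels: argmax over T if present, else over U.

        Ties resolve to the lowest cluster index.
        """
        M = self.T if self.T is not None else self.U
        if M is None:
            raise ValueError("result carries no membership matrix")
        return np.argmax(M, axis=1)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def as_feature_matrix(X: np.ndarray, name: str = "X") -> np.ndarray:
    """Validate and return a 2-D float64 feature matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def squared_distances(
    X: np.ndarray, V: np.ndarray, norm_matrix: Optional[np.ndarray] = None
) -> np.ndarray:
    """Squared A-norm distances between every observation and prototype.

    Entry ``(i, j)`` is ``(x_i - v_j)^T A (x_i - v_j)``. With the default
    identity ``A`` this is the squared Euclidean distance.

    Parameters
    ----------
    X : ndarray, shape (N, q)
    V : ndarray, shape (K, q)
    norm_matrix : ndarray, shape (q, q), optional
        Symmetric positive-definite inducing matrix ``A``.

    Returns
    -------
    ndarray, shape (N, K)
    """
    X = as_feature_matrix(X, "X")
    V = as_feature_matrix(V, "V")
    if X.shape[1] != V.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: X has q={X.shape[1]}, V has q={V.shape[1]}"
        )
    if norm_matrix is None:
        D = cdist(X, V, metric="sqeuclidean")
    else:
        A = np.asarray(norm_matrix, dtype=np.float64)
        if A.shape != (X.shape[1], X.shape[1]):
            raise ValueError("norm_matrix must be q x q")
        if not np.allclose(A, A.T):
            raise ValueError("norm_matrix must be symmetric")
        # Cholesky both validates positive definiteness and lets us fall
        # back to a plain Euclidean cdist in the transformed space.
        L = np.linalg.cholesky(A)
        D = cdist(X @ L, V @ L, metric="sqeuclidean")
    # guard tiny negative round-off
    np.maximum(D, 0.0, out=D)
    return D


def init_prototypes(
    X: np.ndarray, K: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw K distinct data rows, uniformly without replacement.

    Sampling actual observations (rather than box-uniform noise) keeps
    every initial prototype inside the support of the data and so avoids
    empty clusters on the first sweep. When the data contain repeated
    rows (e.g. quantized pixel intensities) the draw is over the unique
    rows, so no two initial prototypes coincide — coincident prototypes
    are a fixed point of every update here and would silently waste a
    cluster. Bit-reproducible given ``rng``.
    """
    X = as_feature_matrix(X)
    N = X.shape[0]
    if not 1 <= K <= N:
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={N}")
    if rng is None:
        rng = np.random.default_rng()
    pool = np.unique(X, axis=0)
    if pool.shape[0] < K:  # fewer distinct patterns than clusters
        pool = X
    idx = rng.choice(pool.shape[0], size=K, replace=False)
    return pool[idx].copy()


def has_converged(V_old: np.ndarray, V_new: np.ndarray, tol: float) -> bool:
    """True iff the maximum absolute entrywise prototype change is < tol."""
    V_old = np.asarray(V_old, dtype=np.float64)
    V_new = np.asarray(V_new, dtype=np.float64)
    if V_old.shape != V_new.shape:
        raise ValueError(
            f"prototype shape mismatch: {V_old.shape} vs {V_new.shape}"
        )
    return bool(np.max(np.abs(V_new - V_old)) < tol)


def check_fuzzy_memberships(U: np.ndarray) -> np.ndarray:
    """Validate a row-stochastic fuzzy membership matrix."""
    U = np.asarray(U, dtype=np.float64)
    if U.ndim != 2:
        raise ValueError("membership matrix must be 2-D")
    if np.any(U < -FUZZY_ROW_SUM_TOL) or np.any(U > 1 + FUZZY_ROW_SUM_TOL):
        raise ValueError("fuzzy memberships must lie in [0, 1]")
    if not np.allclose(U.sum(axis=1), 1.0, atol=FUZZY_ROW_SUM_TOL, rtol=0):
        raise ValueError("fuzzy membership rows must sum to 1")
    return U


def check_typicalities(T: np.ndarray) -> np.ndarray:
    """Validate a possibilistic typicality matrix (box constraint only)."""
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2:
        raise ValueError("typicality matrix must be 2-D")
    if np.any(T < 0) or np.any(T > 1 + FUZZY_ROW_SUM_TOL):
        raise ValueError("typicalities must lie in [0, 1]")
    return T
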