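"""Fuzzy clustering: fuzzy C-means, K-harmonic means, Gustafson-Kessel.

Three iterative estimators sharing one partition container and one
convergence contract (stop when the maximum absolute center change drops
below a threshold, or after ``max_iter`` full update sweeps).  Memberships
always form columns summing to 1; zero distances are handled by flooring
and an explicit coincidence rule (uniform membership over centers the
sample sits on).

* FCM alternates the standard closed-form membership update
  u_ik = [sum_j (d_ik^2 / d_jk^2)^(1/(m-1))]^-1 with the fuzzified center
  mean, minimizing J = sum_ik u_ik^m d_ik^2.
* KHM weights samples by how badly they are covered by all centers (the
  "boosting" weights), which makes it insensitive to initialization.
* GK replaces the Euclidean norm with a per-cluster Mahalanobis norm built
  from a fuzzy covariance matrix under a fixed-volume constraint, so
  ellipsoidal clusters of differing orientation are captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterParams", "FuzzyPartition", "ClusterCollapseError",
    "fcm_membership", "fcm_fit", "khm_membership", "khm_fit",
    "gk_covariance", "gk_fit", "assign_labels",
]

# callback(iteration, U, V) invoked once per completed sweep
SweepCallback = Callable[[int, np.ndarray, np.ndarray], None]

GK_MAX_COND = 1e10


class ClusterCollapseError(RuntimeError):
    """A cluster lost all membership mass (or a singular covariance)."""

    def __init__(self, cluster: int, message: str):
        self.cluster = cluster
        super().__init__(f"cluster {cluster}: {message}")


@dataclass(frozen=True)
class ClusterParams:
    """Shared knobs of the three algorithms.

    Defaults follow the study protocol: c = 6 storage-day clusters,
    fuzzifier m = 2, KHM power p = 2, at most 100 sweeps, center-change
    termination threshold 1e-5.
    """

    n_clusters: int = 6
    fuzzifier: float = 2.0
    khm_power: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    distance_floor: float = 1e-12
    gk_volume: float = 1.0
    gk_cov_regularization: float = 1e-6
    convergence: str = "centers"      # or "memberships"

    def __post_init__(self) -> None:
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        if self.khm_power <= 0:
            raise ValueError("khm_power p must be > 0")
        if not 0 <= self.gk_cov_regularization <= 1:
            raise ValueError("gk_cov_regularization must be in [0, 1]")
        if self.convergence not in ("centers", "memberships"):
            raise ValueError("convergence must be 'centers' or 'memberships'")


@dataclass
class FuzzyPartition:
    """Result of one clustering run.

    ``U`` is clusters x samples; every column sums to 1.  ``covariances``
    is populated by Gustafson-Kessel only.
    """

    U: np.ndarray
    V: np.ndarray
    n_iter: int
    objective_trace: np.ndarray
    converged: bool
    covariances: np.ndarray | None = None


def _check_inputs(X: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(V))):
        raise ValueError("inputs must be finite")
    if X.shape[1] != V.shape[1]:
        raise ValueError("samples and centers have different dimension")
    if V.shape[0] < 2:
        raise ValueError("need at least 2 cluster centers")
    return X, V


def _inverse_power_membership(D: np.ndarray, expo: float,
                              floor: float) -> np.ndarray:
    """u_ik proportional to D_ik^-expo, columns normalized to 1.

    ``D`` is a (clusters x samples) nonnegative dissimilarity.  Columns
    containing a value <= floor get uniform membership over the coincident
    clusters.  Ratios are taken against the per-column minimum so large
    exponents cannot overflow.
    """
    D = np.maximum(D, floor)
    ratio = D / D.min(axis=0, keepdims=True)
    W = ratio ** (-expo)
    U = W / W.sum(axis=0, keepdims=True)
    coincident = D <= floor
    hit = coincident.any(axis=0)
    if hit.any():
        Uc = coincident[:, hit].astype(float)
        U[:, hit] = Uc / Uc.sum(axis=0, keepdims=True)
    return U


def fcm_membership(X: np.ndarray, V: np.ndarray, m: float = 2.0,
                   floor: float = 1e-12) -> np.ndarray:
    """FCM memberships at fixed centers (clusters x samples)."""
    X, V = _check_inputs(X, V)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    D2 = cdist(V, X, "sqeuclidean")
    return _inverse_power_membership(D2, 1.0 / (m - 1.0), floor)


def _fcm_centers(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    Um = U ** m
    mass = Um.sum(axis=1)
    if np.any(mass <= 0):
        raise ClusterCollapseError(int(np.argmin(mass)),
                                   "zero membership mass")
    return (Um @ X) / mass[:, None]


def fcm_fit(X: np.ndarray, init_centers: np.ndarray, params: ClusterParams,
            callback: SweepCallback | None = None) -> FuzzyPartition:
    """Run FCM from the given initial centers.

    One iteration is a full sweep (membership update, then center update);
    convergence is tested after the sweep, so an initialization at a fixed
    point reports ``n_iter == 1``.
    """
    X, V = _check_inputs(X, init_centers)
    m, floor = params.fuzzifier, params.distance_floor
    trace, converged, U_prev = [], False, None
    for it in range(1, params.max_iter + 1):
        D2 = np.maximum(cdist(V, X, "sqeuclidean"), floor)
        U = _inverse_power_membership(D2, 1.0 / (m - 1.0), floor)
        trace.append(float(np.sum(U ** m * D2)))
        V_new = _fcm_centers(X, U, m)
        if callback is not None:
            callback(it, U, V_new)
        if params.convergence == "centers":
            delta = float(np.max(np.abs(V_new - V)))
        else:
            delta = np.inf if U_prev is None else float(np.max(np.abs(U - U_prev)))
        V, U_prev = V_new, U
        if delta < params.tol:
            converged = True
            break
    return FuzzyPartition(U=U, V=V, n_iter=it,
                          objective_trace=np.array(trace), converged=converged)


def khm_membership(X: np.ndarray, V: np.ndarray, p: float = 2.0,
                   floor: float = 1e-12) -> np.ndarray:
    """KHM memberships m(c_j | x_i) = d_ij^(-p-2) / sum_l d_il^(-p-2)."""
    X, V = _check_inputs(X, V)
    if p <= 0:
        raise ValueError("khm_power p must be > 0")
    D = np.sqrt(np.maximum(cdist(V, X, "sqeuclidean"), floor))
    return _inverse_power_membership(D, p + 2.0, np.sqrt(floor))


def khm_fit(X: np.ndarray, init_centers: np.ndarray, params: ClusterParams,
            callback: SweepCallback | None = None) -> FuzzyPartition:
    """Run K-harmonic means from the given initial centers.

    Center update: c_j = sum_i m(c_j|x_i) w(x_i) x_i / sum_i m(c_j|x_i) w(x_i)
    with boosting weights w(x_i) = sum_l d_il^(-p-2) / (sum_l d_il^(-p))^2.
    The objective is the harmonic-mean score sum_i c / sum_j d_ij^(-p).
    """
    X, V = _check_inputs(X, init_centers)
    p, floor = params.khm_power, params.distance_floor
    dfloor = np.sqrt(floor)
    c = V.shape[0]
    trace, converged, U_prev = [], False, None
    for it in range(1, params.max_iter + 1):
        D = np.maximum(np.sqrt(np.maximum(cdist(V, X, "sqeuclidean"), 0.0)),
                       dfloor)
        U = _inverse_power_membership(D, p + 2.0, dfloor)
        inv_p = D ** (-p)                     # (c, n)
        inv_p2 = D ** (-p - 2.0)
        trace.append(float(np.sum(c / inv_p.sum(axis=0))))
        w = inv_p2.sum(axis=0) / inv_p.sum(axis=0) ** 2      # (n,)
        Wgt = U * w[None, :]
        mass = Wgt.sum(axis=1)
        if np.any(mass <= 0):
            raise ClusterCollapseError(int(np.argmin(mass)),
                                       "zero membership mass")
        V_new = (Wgt @ X) / mass[:, None]
        if callback is not None:
            callback(it, U, V_new)
        if params.convergence == "centers":
            delta = float(np.max(np.abs(V_new - V)))
        else:
            delta = np.inf if U_prev is None else float(np.max(np.abs(U - U_prev)))
        V, U_prev = V_new, U
        if delta < params.tol:
            converged = True
            break
    return FuzzyPartition(U=U, V=V, n_iter=it,
                          objective_trace=np.array(trace), converged=converged)


def gk_covariance(X: np.ndarray, U: np.ndarray, V: np.ndarray,
                  m: float = 2.0, regularization: float = 1e-6) -> np.ndarray:
    """Fuzzy covariance matrices F_i, regularized to safe conditioning.

    F_i = sum_k u_ik^m (x_k - v_i)(x_k - v_i)^T / sum_k u_ik^m, then blended
    toward a determinant-scaled identity by ``regularization`` and
    eigenvalue-floored so the condition number stays <= 1e10.
    """
    X, V = _check_inputs(X, V)
    U = np.asarray(U, dtype=float)
    c, q = V.shape
    Um = U ** m
    mass = Um.sum(axis=1)
    F = np.empty((c, q, q))
    for i in range(c):
        if mass[i] <= np.finfo(float).tiny:
            raise ClusterCollapseError(i, "zero membership mass for covariance")
        R = X - V[i]
        Fi = (R * Um[i][:, None]).T @ R / mass[i]
        Fi = 0.5 * (Fi + Fi.T)
        det = np.linalg.det(Fi)
        scale = det ** (1.0 / q) if det > 0 else np.trace(Fi) / q
        if scale <= 0:
            scale = 1.0  # fully degenerate cluster: fall back to identity
        gamma = regularization
        Fi = (1.0 - gamma) * Fi + gamma * scale * np.eye(q)
        vals, vecs = np.linalg.eigh(Fi)
        vmax = vals[-1]
        if vmax <= 0:
            raise ClusterCollapseError(i, "covariance singular after regularization")
        vals = np.maximum(vals, vmax / GK_MAX_COND)
        F[i] = (vecs * vals) @ vecs.T
    return F


def _gk_norms(F: np.ndarray, rho: float) -> np.ndarray:
    """A_i = (rho det F_i)^(1/q) F_i^-1 for every cluster."""
    c, q, _ = F.shape
    A = np.empty_like(F)
    for i in range(c):
        det = np.linalg.det(F[i])
        if det <= 0:
            raise ClusterCollapseError(i, "non-positive covariance determinant")
        A[i] = (rho * det) ** (1.0 / q) * np.linalg.inv(F[i])
    return A


def _mahalanobis_sq(X: np.ndarray, V: np.ndarray, A: np.ndarray) -> np.ndarray:
    """(x_k - v_i)^T A_i (x_k - v_i) for all i, k -> (c, n)."""
    c = V.shape[0]
    D2 = np.empty((c, X.shape[0]))
    for i in range(c):
        R = X - V[i]
        D2[i] = np.einsum("nj,jk,nk->n", R, A[i], R)
    return np.maximum(D2, 0.0)


def gk_fit(X: np.ndarray, init_centers: np.ndarray, params: ClusterParams,
           callback: SweepCallback | None = None) -> FuzzyPartition:
    """Run Gustafson-Kessel clustering from the given initial centers.

    Each sweep: memberships under the current adaptive norms (identity on
    the first sweep), fuzzified center update, fuzzy covariance update,
    new norm matrices A_i = (rho det F_i)^(1/q) F_i^-1.  With the
    covariance blend forced fully to identity (regularization = 1) the
    norms stay Euclidean and the run coincides with FCM.
    """
    X, V = _check_inputs(X, init_centers)
    if X.shape[0] <= V.shape[0]:
        raise ValueError("need more samples than clusters for covariances")
    m, floor = params.fuzzifier, params.distance_floor
    c, q = V.shape
    A = np.broadcast_to(np.eye(q), (c, q, q)).copy()
    trace, converged, U_prev, F = [], False, None, None
    for it in range(1, params.max_iter + 1):
        D2 = np.maximum(_mahalanobis_sq(X, V, A), floor)
        U = _inverse_power_membership(D2, 1.0 / (m - 1.0), floor)
        trace.append(float(np.sum(U ** m * D2)))
        V_new = _fcm_centers(X, U, m)
        F = gk_covariance(X, U, V_new, m, params.gk_cov_regularization)
        A = _gk_norms(F, params.gk_volume)
        if callback is not None:
            callback(it, U, V_new)
        if params.convergence == "centers":
            delta = float(np.max(np.abs(V_new - V)))
        else:
            delta = np.inf if U_prev is None else float(np.max(np.abs(U - U_prev)))
        V, U_prev = V_new, U
        if delta < params.tol:
            converged = True
            break
    return FuzzyPartition(U=U, V=V, n_iter=it,
                          objective_trace=np.array(trace), converged=converged,
                          covariances=F)


def assign_labels(U: np.ndarray) -> np.ndarray:
    """Hard labels by maximum membership; ties go to the lowest cluster index.

    Returns 0-based cluster indices, one per sample (column of U).
    """
    U = np.asarray(U, dtype=float)
    return np.argmax(U, axis=0)
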