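"""Orthogonal linear discriminant analysis (OLDA).

Classical LDA maximizes the Fisher criterion trace(Sw^-1 Sb), which is
undefined when the feature dimension exceeds the sample count (the small
sample size problem typical of full-resolution NIR spectra: d = 1557,
n a few hundred).  The generalized criterion replaces the inverse with the
Moore-Penrose pseudo-inverse of the total scatter,

    G* = argmax_G trace( (G^T St G)^+  G^T Sb G ),

and the resulting transformation is orthogonalized (QR) so the projection
vectors are orthonormal.  The solver works on reduced factorizations of
the centered data and class-mean structure: no d x d matrix is ever
formed, so d >> n is cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["ScatterMatrices", "OLDAModel", "compute_scatter_matrices",
           "fit_olda", "project"]


@dataclass
class ScatterMatrices:
    """Between/within/total scatter of a labeled sample (explicit d x d form).

    Intended for low-dimensional data and for oracle checks; the OLDA fit
    itself never builds these.
    """

    Sb: np.ndarray
    Sw: np.ndarray
    St: np.ndarray
    class_means: np.ndarray
    global_mean: np.ndarray
    classes: np.ndarray


@dataclass
class OLDAModel:
    """Fitted orthonormal discriminant subspace.

    ``G`` has orthonormal columns ordered by decreasing contribution to the
    pseudo-inverse Fisher criterion; ``component_shares`` are each
    component's fraction of ``criterion_value`` and sum to 1.
    """

    G: np.ndarray                 # [d, q]
    mean: np.ndarray              # training global mean [d]
    n_components: int
    criterion_value: float
    component_shares: np.ndarray  # [q]

    def save(self, path) -> None:
        """Serialize as JSON (projection, mean, shares; full precision)."""
        import json
        payload = {
            "G": self.G.tolist(),
            "mean": self.mean.tolist(),
            "n_components": self.n_components,
            "criterion_value": self.criterion_value,
            "component_shares": self.component_shares.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "OLDAModel":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        return cls(G=np.array(payload["G"]), mean=np.array(payload["mean"]),
                   n_components=int(payload["n_components"]),
                   criterion_value=float(payload["criterion_value"]),
                   component_shares=np.array(payload["component_shares"]))


def compute_scatter_matrices(X: np.ndarray, labels: np.ndarray) -> ScatterMatrices:
    """Sb, Sw, St and class means of (X, labels).

    Sb = sum_c n_c (mu_c - mu)(mu_c - mu)^T,
    Sw = sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)^T,  St = Sb + Sw.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    mu = X.mean(axis=0)
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    means = np.empty((classes.size, d))
    for c in range(classes.size):
        Xc = X[inv == c]
        mc = Xc.mean(axis=0)
        means[c] = mc
        dm = mc - mu
        Sb += Xc.shape[0] * np.outer(dm, dm)
        R = Xc - mc
        Sw += R.T @ R
    Xc_all = X - mu
    St = Xc_all.T @ Xc_all
    return ScatterMatrices(Sb=Sb, Sw=Sw, St=St, class_means=means,
                           global_mean=mu, classes=classes)


def fit_olda(X: np.ndarray, labels: np.ndarray,
             n_components: int | None = None) -> OLDAModel:
    """Fit the pseudo-inverse LDA subspace and orthogonalize it.

    Route: economy SVD of the centered data gives the nonzero eigenspace
    of St; the between-class factor Hb (columns sqrt(n_c)(mu_c - mu)) is
    whitened there and its SVD yields the discriminant directions with
    per-direction criterion contributions (squared singular values).  QR
    on the resulting transformation produces orthonormal columns spanning
    the same subspace; the criterion value is invariant to that basis
    change.  Columns are sign-fixed so their largest-magnitude entry is
    positive.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k = classes.size
    if k < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    if n < k:
        raise ValueError("need at least one sample per class and n >= k")
    if n_components is None:
        n_components = k - 1
    if n_components > k - 1:
        raise ValueError(
            f"n_components={n_components} exceeds k-1={k - 1}")

    mu = X.mean(axis=0)
    A = X - mu                                     # [n, d]; St = A^T A
    U_, s, Vt = scipy.linalg.svd(A, full_matrices=False)
    tol = max(n, d) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    if r == 0:
        raise ValueError("all samples identical; no discriminant directions")
    W = Vt[:r].T                                   # [d, r] St eigenvectors
    s_r = s[:r]

    # between-class factor Hb: columns sqrt(n_c) (mu_c - mu)
    Hb = np.empty((d, k))
    for j, c in enumerate(classes):
        Xc = X[labels == c]
        Hb[:, j] = np.sqrt(Xc.shape[0]) * (Xc.mean(axis=0) - mu)

    B = (W.T @ Hb) / s_r[:, None]                  # [r, k] whitened Hb
    P, sig, _ = scipy.linalg.svd(B, full_matrices=False)
    sig_tol = max(B.shape) * np.finfo(float).eps * (sig[0] if sig.size else 0.0)
    rank_b = int(np.sum(sig > sig_tol))
    q = n_components
    if rank_b < q:
        warnings.warn(
            f"between-class rank {rank_b} < requested {q} components; "
            f"reducing to {rank_b}", RuntimeWarning)
        q = rank_b

    G_ulda = W @ (P[:, :q] / s_r[:, None])         # [d, q]
    Q, _ = scipy.linalg.qr(G_ulda, mode="economic")
    # sign convention: largest-magnitude entry of each column positive
    flip = np.sign(Q[np.abs(Q).argmax(axis=0), np.arange(q)])
    flip[flip == 0] = 1.0
    G = Q * flip

    contrib = sig[:q] ** 2
    total = contrib.sum()
    shares = contrib / total if total > 0 else np.full(q, np.nan)
    return OLDAModel(G=G, mean=mu, n_components=q,
                     criterion_value=float(total), component_shares=shares)


def project(model: OLDAModel, X: np.ndarray) -> np.ndarray:
    """Scores = (X - training mean) @ G."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.G.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.G.shape[0]}")
    return (X - model.mean) @ model.G
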