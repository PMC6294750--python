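"""Bundle segmentation by tract shape: pairwise mean-closest-point distance,
spectral embedding into 2-D, and k-means on the embedded points.

Each tract is resampled to a fixed number of equidistant points; the
symmetrized mean-closest-point distance between point sets is the
pseudo-metric, turned into a Gaussian affinity ``exp(-d^2 / sigma^2)``
(sigma defaults to the median off-diagonal distance). Eigenvectors 2 and 3
of the symmetric-normalized affinity give each tract a 2-D coordinate whose
Euclidean geometry reflects shape similarity; a small k-means then cuts the
embedding into bundles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .io import Tract, TractSet

__all__ = [
    "TractAffinity",
    "Embedding2D",
    "resample_tract",
    "tract_distance",
    "distance_matrix",
    "build_affinity",
    "spectral_embed",
    "cluster_tracts",
    "cluster_purity",
]

N_RESAMPLE = 20  # points per tract before distance computation


@dataclass
class TractAffinity:
    distance_matrix: np.ndarray  # (n, n) mm, symmetric, zero diagonal
    affinity_matrix: np.ndarray  # (n, n) in (0, 1]
    sigma: float  # mm


@dataclass
class Embedding2D:
    coordinates: np.ndarray  # (n, 2)
    eigenvalues: np.ndarray  # eigenvalues of the normalized affinity used

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")


def resample_tract(tract: Tract, n: int = N_RESAMPLE) -> np.ndarray:
    """Resample a polyline to ``n`` equidistant (arc-length) points."""
    pts = tract.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n)
    return np.stack([np.interp(si, s, pts[:, k]) for k in range(3)], axis=1)


def tract_distance(a: Tract | np.ndarray, b: Tract | np.ndarray) -> float:
    """Symmetrized mean-closest-point distance (mm) between two tracts."""
    pa = resample_tract(a) if isinstance(a, Tract) else np.asarray(a)
    pb = resample_tract(b) if isinstance(b, Tract) else np.asarray(b)
    d = cdist(pa, pb)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def distance_matrix(ts: TractSet, n_resample: int = N_RESAMPLE) -> np.ndarray:
    pts = [resample_tract(t, n_resample) for t in ts.tracts]
    n = len(pts)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tract_distance(pts[i], pts[j])
    return D


def build_affinity(D: np.ndarray, sigma: float | None = None) -> TractAffinity:
    """Gaussian affinity from a distance matrix; median-heuristic sigma."""
    if sigma is None:
        off = D[np.triu_indices_from(D, k=1)]
        sigma = float(np.median(off)) if off.size else 1.0
        if sigma <= 0:
            sigma = 1.0
    W = np.exp(-(D**2) / sigma**2)
    return TractAffinity(distance_matrix=D, affinity_matrix=W, sigma=sigma)


def _fix_eigenvector_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for c in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, c])))
        if V[i, c] < 0:
            V[:, c] = -V[:, c]
    return V


def spectral_embed(
    ts: TractSet, sigma: float | None = None, affinity: TractAffinity | None = None
) -> Embedding2D:
    """Embed each tract as a 2-D point from the normalized affinity spectrum.

    Uses eigenvectors 2 and 3 (the first is the trivial stationary vector)
    of ``D^{-1/2} W D^{-1/2}``. A disconnected affinity graph (all
    off-diagonal similarities ~0) still returns an embedding, with a
    warning.
    """
    if len(ts) < 3:
        raise ValueError("spectral embedding needs at least 3 tracts")
    if affinity is None:
        affinity = build_affinity(distance_matrix(ts), sigma=sigma)
    W = affinity.affinity_matrix
    off = W - np.diag(np.diag(W))
    if np.all(off < 1e-12):
        warnings.warn("affinity graph is disconnected (all similarities ~ 0)")
    if np.allclose(W, W[0, 0], atol=1e-12):
        # all tracts mutually identical: every embedding is degenerate;
        # map them to one point
        return Embedding2D(
            coordinates=np.zeros((len(ts), 2)), eigenvalues=np.array([1.0, 0.0, 0.0])
        )
    deg = W.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
    M = (W * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    M = 0.5 * (M + M.T)
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    V = _fix_eigenvector_signs(evecs[:, 1:3])
    # back to the random-walk eigenvectors: constant within a tight bundle
    coords = V * d_inv_sqrt[:, None]
    coords /= np.linalg.norm(coords, axis=0, keepdims=True).clip(1e-300)
    return Embedding2D(coordinates=coords, eigenvalues=evals[:3])


def cluster_tracts(e: Embedding2D, k: int = 2, seed: int = 0) -> np.ndarray:
    """k-means labels on the embedded points; deterministic given ``seed``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(e.coordinates)
    if k > n:
        raise ValueError(f"k={k} exceeds number of tracts ({n})")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(e.coordinates)


def cluster_purity(labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of tracts whose cluster's majority truth label matches theirs."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    correct = 0
    for c in np.unique(labels):
        members = truth[labels == c]
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(truth)
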