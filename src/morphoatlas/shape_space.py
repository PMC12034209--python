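"""Shape spaces from momenta (kernel PCA) and from landmarks (ordinary PCA).

The momenta produced by atlas estimation live on a curved manifold of
diffeomorphisms; kernel PCA with a Gaussian Gram matrix linearises them
into at most n-1 ordered axes whose eigenvalue spectrum is directly
comparable with the spectrum of a landmark PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["ShapeScores", "momenta_matrix", "kpca", "pca_scores", "variance_spectrum"]


@dataclass
class ShapeScores:
    """Specimens x axes score matrix with its eigenvalue spectrum."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    axis_kind: str = "kpca"
    specimen_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not self.specimen_ids:
            self.specimen_ids = [str(i) for i in range(len(self.scores))]

    @property
    def n_specimens(self) -> int:
        return len(self.scores)

    @property
    def percent_variance(self) -> np.ndarray:
        return variance_spectrum(self)

    def row(self, specimen_id: str) -> np.ndarray:
        try:
            i = self.specimen_ids.index(specimen_id)
        except ValueError as exc:
            raise KeyError(f"unknown specimen: {specimen_id}") from exc
        return self.scores[i]


def momenta_matrix(momenta) -> np.ndarray:
    """Flatten per-specimen momenta (n, p, 3) into an (n, 3p) matrix
    (control-point-major, then x, y, z)."""
    values = getattr(momenta, "values", momenta)
    values = np.asarray(values, dtype=float)
    return values.reshape(values.shape[0], -1)


def _fix_signs_by_scores(scores: np.ndarray) -> np.ndarray:
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col
    return scores


def kpca(
    momenta,
    gamma: float | str = 2.5e-6,
    n_axes: int | None = None,
    seed: int | None = None,
) -> ShapeScores:
    """Kernel PCA of flattened momenta.

    Gram matrix G_ij = exp(-gamma |m_i - m_j|^2), double-centred, then a
    dense symmetric eigendecomposition; scores are eigenvectors scaled by
    sqrt(eigenvalue), sorted by eigenvalue descending, each axis signed so
    its largest-magnitude score is positive.  ``gamma='auto'`` uses
    1 / median squared pairwise distance, which adapts the kernel width to
    the magnitude of the momenta at hand.  ``seed`` is accepted for
    interface symmetry; the dense solver used at these problem sizes is
    deterministic.
    """
    M = momenta_matrix(momenta)
    n = len(M)
    if n < 2:
        raise ValueError("need >= 2 specimens")
    d2 = squareform(pdist(M, metric="sqeuclidean"))
    if gamma == "auto":
        off = d2[np.triu_indices(n, 1)]
        med = np.median(off[off > 0]) if np.any(off > 0) else 1.0
        gamma = 1.0 / med
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    G = np.exp(-gamma * d2)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite Gram entries")
    J = np.eye(n) - np.ones((n, n)) / n
    Gc = J @ G @ J
    Gc = 0.5 * (Gc + Gc.T)
    eigval, eigvec = np.linalg.eigh(Gc)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k_max = n - 1
    k = k_max if n_axes is None else min(n_axes, k_max)
    eigval = np.clip(eigval[:k], 0.0, None)
    if eigval.size and eigval[0] > 0:
        eigval[eigval < 1e-12 * eigval[0]] = 0.0  # numerical null space
    scores = eigvec[:, :k] * np.sqrt(eigval)[None, :]
    scores = _fix_signs_by_scores(scores)
    ids = list(getattr(momenta, "specimen_ids", [])) or None
    return ShapeScores(scores, eigval, axis_kind="kpca", specimen_ids=ids or [])


def pca_scores(data: np.ndarray, axis_kind: str = "pca") -> ShapeScores:
    """Ordinary PCA by SVD of the centred data matrix; <= n-1 axes with
    non-negative eigenvalues (variances) sorted descending, each axis signed
    so its largest-magnitude loading is positive."""
    X = np.asarray(data, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need >= 2 specimens")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, Xc.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    eigval = s**2 / (n - 1)
    scores = U * s[None, :]
    for a in range(k):
        load = Vt[a]
        if load[np.argmax(np.abs(load))] < 0:
            Vt[a] = -load
            scores[:, a] = -scores[:, a]
    return ShapeScores(scores, eigval, axis_kind=axis_kind)


def variance_spectrum(scores: ShapeScores) -> np.ndarray:
    """percent_k = 100 eigval_k / sum of positive eigenvalues."""
    ev = np.clip(scores.eigenvalues, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    return 100.0 * ev / total
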