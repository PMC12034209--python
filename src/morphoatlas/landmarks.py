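"""The manual-landmarking branch.

Homologous point configurations (fixed landmarks plus curve semilandmarks)
are resampled, slid to minimise thin-plate-spline bending energy,
superimposed by generalized Procrustes analysis, and decomposed by ordinary
PCA.  Thin-plate splines also drive the heatmap warps that compare the two
morphometric branches on the same surface.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, LandmarkSchemeError
from .mesh import TriangleMesh, centroid_size, rigid_transform
from .shape_space import ShapeScores, pca_scores

__all__ = [
    "LandmarkConfig",
    "ProcrustesResult",
    "TPSModel",
    "read_landmarks",
    "write_landmarks",
    "resample_curve",
    "bending_energy_matrix",
    "fit_tps",
    "tps_warp",
    "slide_semilandmarks",
    "generalized_procrustes",
    "mirror_configuration",
    "landmark_pca",
]


@dataclass
class LandmarkConfig:
    """Ordered homologous 3D points for one specimen.

    ``roles`` tags each point (``fixed``, ``curve:<k>`` or ``tracked``);
    ``curves`` lists, per curve, the ordered point indices it comprises.
    """

    points: np.ndarray
    roles: list = field(default_factory=list)
    curves: list = field(default_factory=list)
    specimen_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not self.roles:
            self.roles = ["fixed"] * len(self.points)
        if len(self.roles) != len(self.points):
            raise LandmarkSchemeError("one role per point required")
        for curve in self.curves:
            if len(curve) < 2:
                raise LandmarkSchemeError("each curve needs at least 2 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def copy(self) -> "LandmarkConfig":
        return LandmarkConfig(
            self.points.copy(), list(self.roles), [list(c) for c in self.curves], self.specimen_id
        )


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (n, k, 3) shape coordinates
    mean_shape: np.ndarray  # (k, 3) consensus, centred, unit centroid size
    centroid_sizes: np.ndarray  # (n,) in mm


def write_landmarks(config: LandmarkConfig, path) -> None:
    with open(str(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["landmark_id", "x", "y", "z"])
        for i, p in enumerate(config.points):
            w.writerow([i, f"{p[0]:.10g}", f"{p[1]:.10g}", f"{p[2]:.10g}"])


def read_landmarks(path, specimen_id: str = "") -> LandmarkConfig:
    pts = []
    with open(str(path)) as fh:
        for row in csv.DictReader(fh):
            pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
    return LandmarkConfig(np.array(pts), specimen_id=specimen_id)


# ---------------------------------------------------------------------------
# Curves


def resample_curve(polyline: np.ndarray, k: int) -> np.ndarray:
    """k points at equal arc-length spacing along a polyline; endpoints exact."""
    pts = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if k < 2 or len(pts) < 2:
        raise ValueError("need k >= 2 and at least 2 polyline points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length polyline")
    targets = np.linspace(0.0, total, k)
    out = np.column_stack([np.interp(targets, cum, pts[:, d]) for d in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return out


# ---------------------------------------------------------------------------
# Thin-plate splines (3D, kernel U(r) = -r)


def _tps_system(source: np.ndarray):
    n = len(source)
    r = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=2)
    K = -r
    P = np.column_stack([np.ones(n), source])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    return L, K


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """Matrix B with bending energy tr(Y' B Y) for targets Y at these sources."""
    n = len(source)
    L, _ = _tps_system(np.asarray(source, dtype=float))
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise LandmarkSchemeError("singular TPS system (duplicated landmarks?)") from exc
    B = Linv[:n, :n]
    return 0.5 * (B + B.T)


@dataclass
class TPSModel:
    source: np.ndarray
    target: np.ndarray
    weights: np.ndarray  # (n, 3) non-affine coefficients
    affine: np.ndarray  # (4, 3): row 0 translation, rows 1..3 linear
    bending_energy: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        r = np.linalg.norm(pts[:, None, :] - self.source[None, :, :], axis=2)
        U = -r
        P = np.column_stack([np.ones(len(pts)), pts])
        return U @ self.weights + P @ self.affine


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Exact 3D TPS interpolant source -> target with kernel U(r) = -r."""
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    n = len(src)
    if n < 4 or len(tgt) != n:
        raise LandmarkSchemeError("need >= 4 paired landmarks")
    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if sv[2] <= 1e-10 * max(sv[0], 1e-300):
        raise LandmarkSchemeError("coplanar source configuration")
    L, K = _tps_system(src)
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise LandmarkSchemeError("singular TPS system (duplicated landmarks?)") from exc
    W, Aff = sol[:n], sol[n:]
    energy = float(np.einsum("id,ij,jd->", W, K, W))
    return TPSModel(source=src, target=tgt, weights=W, affine=Aff, bending_energy=max(energy, 0.0))


def tps_warp(mesh: TriangleMesh, source_lm, target_lm):
    """Warp every mesh vertex through the landmark-interpolating spline."""
    src = np.asarray(getattr(source_lm, "points", source_lm), dtype=float)
    tgt = np.asarray(getattr(target_lm, "points", target_lm), dtype=float)
    model = fit_tps(src, tgt)
    out = mesh.copy()
    out.vertices = model.transform(mesh.vertices)
    return out, model


# ---------------------------------------------------------------------------
# Semilandmark sliding


def slide_semilandmarks(
    configs: list[LandmarkConfig],
    reference: LandmarkConfig,
    n_sweeps: int = 3,
) -> list[LandmarkConfig]:
    """Slide curve semilandmarks along reference tangent lines to minimise
    TPS bending energy against the reference.

    Curve endpoints and fixed landmarks never move.  Each sweep performs one
    Gauss-Seidel pass of exact 1-D minimisations, so the bending energy is
    monotonically non-increasing.
    """
    ref = reference.points
    B = bending_energy_matrix(ref)
    slide_idx, tangents = [], []
    for curve in reference.curves:
        for pos in range(1, len(curve) - 1):
            j = curve[pos]
            t = ref[curve[pos + 1]] - ref[curve[pos - 1]]
            norm = np.linalg.norm(t)
            if norm <= 1e-12:
                raise LandmarkSchemeError(f"degenerate tangent at curve point {j}")
            slide_idx.append(j)
            tangents.append(t / norm)
    out = []
    for cfg in configs:
        Y = cfg.points.copy()
        BY = B @ Y
        for _ in range(n_sweeps):
            for j, t in zip(slide_idx, tangents):
                bjj = B[j, j]
                if bjj <= 1e-14:
                    continue
                alpha = -float(t @ BY[j]) / bjj
                dy = alpha * t
                Y[j] += dy
                BY += np.outer(B[:, j], dy)
        new = cfg.copy()
        new.points = Y
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis


def generalized_procrustes(configs, with_scale: bool = True, max_iter: int = 200) -> ProcrustesResult:
    """Iterative superimposition: centre, (optionally) scale to unit centroid
    size, rotate to the consensus, re-estimate the consensus, until the
    consensus changes by less than 1e-10."""
    pts = [np.asarray(getattr(c, "points", c), dtype=float) for c in configs]
    if len(pts) < 2 or any(p.shape != pts[0].shape for p in pts) or pts[0].shape[0] < 3:
        raise AlignmentError("need >= 2 configurations with equal landmark counts >= 3")
    sizes = np.array([centroid_size(p) for p in pts])
    if np.any(sizes <= 0):
        raise AlignmentError("zero centroid size (all landmarks coincident)")
    X = np.stack([p - p.mean(axis=0) for p in pts])
    if with_scale:
        X = X / sizes[:, None, None]
    consensus = X[0] / centroid_size(X[0])
    for _ in range(max_iter):
        for i in range(len(X)):
            _, R, _ = rigid_transform(X[i], consensus)
            X[i] = X[i] @ R.T
        new = X.mean(axis=0)
        new = new - new.mean(axis=0)
        new = new / centroid_size(new)
        if np.linalg.norm(new - consensus) < 1e-10:
            consensus = new
            break
        consensus = new
    # Canonical orientation: rotate everything into the consensus principal
    # frame with a deterministic sign rule, so the result is invariant to
    # rigid motions of the inputs (not merely invariant up to rotation).
    _, _, Vt = np.linalg.svd(consensus - consensus.mean(axis=0))
    V = Vt.T
    rot = consensus @ V
    for k in range(3):
        if rot[np.argmax(np.abs(rot[:, k])), k] < 0:
            V[:, k] = -V[:, k]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    consensus = consensus @ V
    for i in range(len(X)):
        _, R, _ = rigid_transform(X[i], consensus)
        X[i] = X[i] @ R.T
    return ProcrustesResult(aligned=X, mean_shape=consensus, centroid_sizes=sizes)


# ---------------------------------------------------------------------------
# Mirroring


def mirror_configuration(
    config: LandmarkConfig, midline_indices, side_indices
) -> LandmarkConfig:
    """Append reflections of one-sided points across the best-fit midline plane."""
    midline = np.asarray(midline_indices, dtype=int)
    side = np.asarray(side_indices, dtype=int)
    if len(midline) < 3:
        raise LandmarkSchemeError("need >= 3 midline points to define the plane")
    mpts = config.points[midline]
    centre = mpts.mean(axis=0)
    _, sv, Vt = np.linalg.svd(mpts - centre)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300):
        raise LandmarkSchemeError("midline points are collinear; plane undefined")
    normal = Vt[2]
    pts = config.points[side]
    refl = pts - 2.0 * ((pts - centre) @ normal)[:, None] * normal[None, :]
    out = config.copy()
    out.points = np.vstack([config.points, refl])
    out.roles = list(config.roles) + ["mirrored"] * len(side)
    return out


# ---------------------------------------------------------------------------
# Ordinary PCA of aligned coordinates


def landmark_pca(proc: ProcrustesResult) -> ShapeScores:
    """PCA of the flattened Procrustes-aligned coordinates (<= n-1 axes)."""
    n = proc.aligned.shape[0]
    flat = proc.aligned.reshape(n, -1)
    return pca_scores(flat, axis_kind="pca")
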