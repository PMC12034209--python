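"""Triangle-mesh I/O and standardisation.

Meshes are the unit of exchange for the whole pipeline: specimens enter as
(possibly open) triangulated surfaces in mm, are standardised to watertight
surfaces at a fixed face budget, and are aligned onto landmark configurations
before atlas estimation.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh
from scipy import ndimage
from skimage import measure as _skmeasure

from .errors import AlignmentError, MeshFormatError, MeshIndexError, MeshTopologyError

__all__ = [
    "TriangleMesh",
    "OrientedFaceSet",
    "VoxelGrid",
    "read_mesh",
    "write_mesh",
    "oriented_face_set",
    "close_watertight",
    "decimate_quadric",
    "align_mesh_to_landmarks",
    "rigid_transform",
    "centroid_size",
    "closest_point_distance",
]


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) in mm and ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshIndexError(
                f"face index out of range for {len(self.vertices)} vertices"
            )
        if self.faces.size:
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise MeshTopologyError("face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.specimen_id)

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def edge_counts(self) -> dict:
        counts: dict = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (a, b) if a < b else (b, a)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_watertight(self) -> bool:
        counts = self.edge_counts()
        return bool(counts) and all(c == 2 for c in counts.values())

    def euler_characteristic(self) -> int:
        n_used = len(np.unique(self.faces)) if self.faces.size else 0
        n_edges = len(self.edge_counts())
        return n_used - n_edges + self.n_faces

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class OrientedFaceSet:
    """Per-face centres c_p and area-weighted normals n_p (|n_p| = face area)."""

    centres: np.ndarray
    normals: np.ndarray

    @property
    def areas(self) -> np.ndarray:
        return np.linalg.norm(self.normals, axis=1)


@dataclass
class VoxelGrid:
    """A boolean occupancy lattice with a world-space anchor."""

    origin: np.ndarray
    voxel_size: float
    occupancy: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# I/O


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write an ascii PLY file.

    The writer is deliberately plain-text and format-stable so that the same
    mesh always produces byte-identical output.
    """
    path = str(path)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path, specimen_id: str | None = None) -> TriangleMesh:
    """Read a PLY (ascii or binary little-endian) or OBJ file."""
    path = str(path)
    lower = path.lower()
    if lower.endswith(".ply"):
        file_type = "ply"
    elif lower.endswith(".obj"):
        file_type = "obj"
    else:
        raise MeshFormatError(f"unsupported mesh format: {path}")
    try:
        loaded = _trimesh.load(path, file_type=file_type, process=False, force="mesh")
    except (MeshIndexError, MeshTopologyError):
        raise
    except FileNotFoundError:
        raise
    except Exception as exc:  # trimesh raises assorted types for bad files
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise MeshFormatError(f"no triangulated surface in {path}")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise MeshIndexError(f"face index out of range in {path}")
    sid = specimen_id if specimen_id is not None else ""
    return TriangleMesh(vertices, faces, sid)


# ---------------------------------------------------------------------------
# Oriented face measures


def oriented_face_set(mesh: TriangleMesh) -> OrientedFaceSet:
    """Face centres and area-magnitude normals.

    centre = (v1+v2+v3)/3 and normal = 0.5 (v2-v1) x (v3-v1); the normal's
    direction follows the face winding and its magnitude equals the face
    area, the convention the current/varifold sums consume.
    """
    tri = mesh.vertices[mesh.faces]
    centres = tri.mean(axis=1)
    normals = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = np.linalg.norm(normals, axis=1)
    n_zero = int(np.sum(areas <= 0.0))
    if n_zero:
        warnings.warn(f"{n_zero} degenerate (zero-area) face(s)", RuntimeWarning)
    return OrientedFaceSet(centres=centres, normals=normals)


# ---------------------------------------------------------------------------
# Watertight standardisation


def voxelize_surface(mesh: TriangleMesh, voxel_size: float, pad: float) -> VoxelGrid:
    """Mark every voxel touched by the surface on a padded axis-aligned grid."""
    lo, hi = mesh.bounds()
    origin = lo - pad
    extent = hi - lo + 2.0 * pad
    shape = np.ceil(extent / voxel_size).astype(int) + 1
    occupancy = np.zeros(shape, dtype=bool)
    verts, faces = mesh.vertices, mesh.faces
    if faces.size:
        verts, faces = _trimesh.remesh.subdivide_to_size(
            verts, faces, max_edge=voxel_size, max_iter=32
        )
    pts = np.vstack([verts, verts[faces].mean(axis=1)]) if len(faces) else verts
    idx = np.floor((pts - origin) / voxel_size).astype(int)
    idx = np.clip(idx, 0, shape - 1)
    occupancy[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelGrid(origin=origin, voxel_size=voxel_size, occupancy=occupancy)


def close_watertight(
    mesh: TriangleMesh,
    voxel_size: float | None = None,
    heal_radius: float | None = None,
) -> TriangleMesh:
    """Standardise a possibly-open mesh to a watertight surface.

    The surface is rasterised on a padded voxel grid, morphologically closed
    at scale ``heal_radius`` (sealing boundary holes up to roughly twice that
    radius), the exterior is identified by flood fill from the grid boundary,
    and the output surface is extracted as the ``heal_radius`` level set of
    the distance-to-exterior field.  The result is always a closed,
    consistently outward-oriented surface within a couple of voxels of the
    input away from healed holes.
    """
    if mesh.n_faces == 0:
        raise MeshTopologyError("empty mesh")
    lo, hi = mesh.bounds()
    diag = float(np.linalg.norm(hi - lo))
    if diag <= 0:
        raise MeshTopologyError("degenerate (zero-extent) mesh")
    if voxel_size is None:
        voxel_size = diag / 200.0
    if not (0 < voxel_size <= diag / 10.0):
        raise ValueError("voxel_size must be positive and at most diagonal/10")
    if heal_radius is None:
        heal_radius = 0.1 * diag
    heal = max(float(heal_radius), 2.0 * voxel_size)

    grid = voxelize_surface(mesh, voxel_size, pad=heal + 3.0 * voxel_size)
    surf = grid.occupancy
    # Dilate the surface shell by the healing radius.
    dist_to_surf = ndimage.distance_transform_edt(~surf, sampling=voxel_size)
    dilated = dist_to_surf <= heal
    # Exterior = connected components of the complement touching the border.
    labels, n_labels = ndimage.label(~dilated)
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    exterior = np.isin(labels, sorted(border_labels))
    solid = ~exterior
    # Erode back by the same radius via the distance-to-exterior field and
    # extract its level set (sub-voxel accurate through linear interpolation).
    dist_in = ndimage.distance_transform_edt(solid, sampling=voxel_size)
    if dist_in.max() <= heal:
        raise MeshTopologyError("voxel grid too coarse: no interior survives closing")
    # Take the occupancy eroded back by the healing radius and extract a
    # smoothed-indicator isosurface: smoothing suppresses voxel-scale
    # faceting without moving the surface by more than a fraction of a voxel.
    occupancy = dist_in > heal
    field = ndimage.gaussian_filter(occupancy.astype(float), sigma=1.0)
    verts, faces, _, _ = _skmeasure.marching_cubes(
        field, level=0.5, spacing=(voxel_size,) * 3
    )
    verts = verts + grid.origin
    out = TriangleMesh(verts, faces.astype(np.int64), mesh.specimen_id)
    if out.n_faces == 0:
        raise MeshTopologyError("voxel grid too coarse: empty isosurface")
    # Orient outward (positive enclosed volume).
    if _signed_volume(out) < 0:
        out.faces = out.faces[:, ::-1].copy()
    return out


def _signed_volume(mesh: TriangleMesh) -> float:
    tri = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)


# ---------------------------------------------------------------------------
# Quadric decimation


def decimate_quadric(mesh: TriangleMesh, target_faces: int) -> TriangleMesh:
    """Quadric-error edge-collapse decimation to a face budget.

    Greedy collapse of the cheapest edge under the Garland–Heckbert quadric
    metric, with a link-condition check so manifoldness is preserved and a
    normal-flip rejection so the surface cannot fold.  Boundary vertices are
    never collapsed, so open meshes keep their boundary exactly.  If the
    target cannot be reached without violating these guards the achieved
    count is returned.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    if target_faces >= mesh.n_faces:
        return mesh.copy()

    V = mesh.vertices.copy()
    faces = {i: tuple(int(x) for x in f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set] = {i: set() for i in range(len(V))}
    for fid, f in faces.items():
        for v in f:
            vert_faces[v].add(fid)

    # Boundary vertices (any edge used once).
    edge_use: dict = {}
    for f in faces.values():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            edge_use[key] = edge_use.get(key, 0) + 1
    boundary = set()
    for (a, b), c in edge_use.items():
        if c != 2:
            boundary.add(a)
            boundary.add(b)

    # Per-vertex quadrics, area weighted.
    Q = np.zeros((len(V), 4, 4))
    for f in faces.values():
        p0, p1, p2 = V[f[0]], V[f[1]], V[f[2]]
        n = np.cross(p1 - p0, p2 - p0)
        area = 0.5 * np.linalg.norm(n)
        if area <= 0:
            continue
        n = n / (2.0 * area)
        plane = np.append(n, -n @ p0)
        K = np.outer(plane, plane) * area
        for v in f:
            Q[v] += K

    version = np.zeros(len(V), dtype=np.int64)

    def neighbours(v: int) -> set:
        out = set()
        for fid in vert_faces[v]:
            out.update(faces[fid])
        out.discard(v)
        return out

    def edge_cost(i: int, j: int):
        Qe = Q[i] + Q[j]
        A = Qe[:3, :3]
        b = -Qe[:3, 3]
        candidates = [V[i], V[j], 0.5 * (V[i] + V[j])]
        try:
            x = np.linalg.solve(A, b)
            if np.all(np.isfinite(x)):
                candidates.insert(0, x)
        except np.linalg.LinAlgError:
            pass
        best, best_cost = None, np.inf
        for c in candidates:
            h = np.append(c, 1.0)
            cost = float(h @ Qe @ h)
            if cost < best_cost:
                best, best_cost = c, cost
        return best_cost, np.asarray(best)

    heap: list = []

    def push_edge(i: int, j: int) -> None:
        if i in boundary or j in boundary:
            return
        a, b = (i, j) if i < j else (j, i)
        cost, pos = edge_cost(a, b)
        heapq.heappush(heap, (cost, a, b, int(version[a]), int(version[b]), pos))

    seen = set()
    for f in faces.values():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            if key not in seen:
                seen.add(key)
                push_edge(*key)
    del seen

    n_faces_alive = len(faces)
    while n_faces_alive > target_faces and heap:
        cost, i, j, vi, vj, pos = heapq.heappop(heap)
        if version[i] != vi or version[j] != vj:
            continue
        if not vert_faces.get(i) or not vert_faces.get(j):
            continue
        shared = vert_faces[i] & vert_faces[j]
        if len(shared) != 2:
            continue
        # Link condition: common neighbours must be exactly the two apexes.
        apex = set()
        for fid in shared:
            apex.update(v for v in faces[fid] if v not in (i, j))
        if neighbours(i) & neighbours(j) != apex:
            continue
        # Normal-flip / degeneracy rejection on every surviving incident face.
        ok = True
        for fid in (vert_faces[i] | vert_faces[j]) - shared:
            f = faces[fid]
            old = V[list(f)]
            new = np.array([pos if v in (i, j) else V[v] for v in f])
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            if n_old @ n_new <= 1e-12 * max(n_old @ n_old, 1e-300):
                ok = False
                break
        if not ok:
            continue
        # Apply the collapse: merge j into i at pos.
        V[i] = pos
        Q[i] = Q[i] + Q[j]
        for fid in shared:
            for v in faces[fid]:
                vert_faces[v].discard(fid)
            del faces[fid]
            n_faces_alive -= 1
        for fid in list(vert_faces[j]):
            f = faces[fid]
            faces[fid] = tuple(i if v == j else v for v in f)
            vert_faces[i].add(fid)
            vert_faces[j].discard(fid)
        version[i] += 1
        version[j] += 1
        for k in neighbours(i):
            push_edge(i, k)

    used = sorted({v for f in faces.values() for v in f})
    remap = {v: k for k, v in enumerate(used)}
    new_faces = np.array(
        [[remap[a], remap[b], remap[c]] for (a, b, c) in faces.values()], dtype=np.int64
    )
    return TriangleMesh(V[used], new_faces, mesh.specimen_id)


# ---------------------------------------------------------------------------
# Landmark-driven alignment


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distance of landmarks to their centroid."""
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(np.sum((pts - pts.mean(axis=0)) ** 2)))


def rigid_transform(source: np.ndarray, target: np.ndarray, with_scale: bool = False):
    """Least-squares similarity transform source -> target (no reflection).

    Returns ``(scale, rotation, translation)`` such that
    ``scale * source @ rotation.T + translation`` best fits ``target``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise AlignmentError("need >= 3 paired landmarks")
    sc = src - src.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300):
        raise AlignmentError("collinear landmark configuration")
    scale = centroid_size(tgt) / centroid_size(src) if with_scale else 1.0
    src_s = src * scale
    mu_s, mu_t = src_s.mean(axis=0), tgt.mean(axis=0)
    H = (src_s - mu_s).T @ (tgt - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return scale, R, t


def align_mesh_to_landmarks(
    mesh: TriangleMesh,
    source_lm,
    target_lm,
    with_scale: bool = False,
) -> TriangleMesh:
    """Apply the landmark-fitted rigid (optionally scaled) transform to a mesh."""
    src = np.asarray(getattr(source_lm, "points", source_lm), dtype=float)
    tgt = np.asarray(getattr(target_lm, "points", target_lm), dtype=float)
    scale, R, t = rigid_transform(src, tgt, with_scale=with_scale)
    verts = (scale * mesh.vertices) @ R.T + t
    return replace(mesh.copy(), vertices=verts)


# ---------------------------------------------------------------------------
# Point-to-surface distance (used for heatmap fields and Hausdorff checks)


def closest_point_distance(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Distance from each point to the nearest point on the mesh surface.

    Vectorised point-to-triangle projection over all (point, face) pairs;
    exact, and adequate at the face counts this package works with.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.vertices[mesh.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    d2 = np.full((len(P), len(tri)), np.inf)
    # Process in point blocks to bound memory.
    block = max(1, int(4e6 / max(len(tri), 1)))
    for s in range(0, len(P), block):
        p = P[s : s + block][:, None, :]
        ab = (b - a)[None]
        ac = (c - a)[None]
        ap = p - a[None]
        d1 = np.einsum("pfk,pfk->pf", ab, ap)
        d2_ = np.einsum("pfk,pfk->pf", ac, ap)
        bp = p - b[None]
        d3 = np.einsum("pfk,pfk->pf", ab, bp)
        d4 = np.einsum("pfk,pfk->pf", ac, bp)
        cp = p - c[None]
        d5 = np.einsum("pfk,pfk->pf", ab, cp)
        d6 = np.einsum("pfk,pfk->pf", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2_ - d1 * d6
        vc = d1 * d4 - d3 * d2_
        denom = va + vb + vc
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(denom != 0, vb / denom, 0.0)
            w = np.where(denom != 0, vc / denom, 0.0)
            v1 = np.clip(np.where(d1 + d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
            w2 = np.clip(np.where(d2_ + d6 != 0, d2_ / (d2_ - d6), 0.0), 0, 1)
            denom_bc = (d4 - d3) + (d5 - d6)
            w3 = np.clip(
                np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0), 0, 1
            )
        # Region tests per Ericson.
        q = np.empty_like(p + np.zeros_like(a)[None])
        q[:] = a[None] + v[..., None] * ab + w[..., None] * ac  # interior guess
        reg_a = (d1 <= 0) & (d2_ <= 0)
        reg_b = (d3 >= 0) & (d4 <= d3)
        reg_c = (d6 >= 0) & (d5 <= d6)
        reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        reg_ac = (vb <= 0) & (d2_ >= 0) & (d6 <= 0)
        reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        q = np.where(reg_bc[..., None], b[None] + w3[..., None] * (c - b)[None], q)
        q = np.where(reg_ac[..., None], a[None] + w2[..., None] * ac, q)
        q = np.where(reg_ab[..., None], a[None] + v1[..., None] * ab, q)
        q = np.where(reg_c[..., None], c[None] + np.zeros_like(q), q)
        q = np.where(reg_b[..., None], b[None] + np.zeros_like(q), q)
        q = np.where(reg_a[..., None], a[None] + np.zeros_like(q), q)
        d2[s : s + block] = np.einsum("pfk,pfk->pf", p - q, p - q)
    return np.sqrt(d2.min(axis=1))
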