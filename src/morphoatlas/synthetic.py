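"""Seeded synthetic study populations with known deformation structure.

Populations of closed, cranium-scale triangulated surfaces are produced by
geodesic shooting of a template icosphere under momenta composed of three
ingredients with known ground truth: a smooth elongation pattern along one
axis (the dolichocephalic-brachycephalic analogue), clade-structured
variation evolved by Brownian motion on a pure-birth phylogeny, and
independent individual noise.  Landmark configurations are tracked template
vertices carried through the same flow, so they are exactly homologous by
construction.  A modality artifact (an open patch, emulating CT meshes with
missing surface) can be introduced on a seeded subset of specimens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .atlas import ControlPointSet, geodesic_shoot, flow_points, init_control_points, velocity_field
from .errors import MeshTopologyError
from .landmarks import LandmarkConfig, write_landmarks
from .macroevo import Phylogeny, phylo_covariance
from .mesh import TriangleMesh, write_mesh

__all__ = [
    "PopulationSpec",
    "SyntheticStudy",
    "LandmarkScheme",
    "generate_base_mesh",
    "generate_phylogeny",
    "build_landmark_scheme",
    "stretch_pattern",
    "simulate_population_momenta",
    "synthesize_specimen",
    "introduce_modality_artifact",
    "clade_groups",
    "build_study",
]


@dataclass
class PopulationSpec:
    """Study-population parameters; the defaults are the study conditions."""

    n_specimens: int = 20
    base_radius: float = 40.0  # mm; an 80 mm cranium-scale object
    subdivision_level: int = 3
    kernel_width_true: float = 25.0  # mm
    elongation_sd: float = 0.15
    bm_rate: float = 1.0  # mm^2 momenta variance per unit branch length
    individual_noise_sd: float = 0.5  # mm per momentum coordinate
    open_fraction: float = 0.0
    n_groups: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if not (0.0 <= self.open_fraction <= 1.0):
            raise ValueError("open_fraction must be in [0, 1]")
        if min(self.elongation_sd, self.bm_rate, self.individual_noise_sd) < 0:
            raise ValueError("variance parameters must be non-negative")


@dataclass
class LandmarkScheme:
    """Template vertex indices tracked as landmarks, with roles and curves."""

    vertex_indices: np.ndarray
    roles: list
    curves: list


@dataclass
class SyntheticStudy:
    meshes: list
    landmarks: list
    true_momenta: np.ndarray  # (n, p, 3) at the true control grid
    elongation_coefficients: np.ndarray
    modality_labels: list  # "open" | "closed" per specimen
    group_labels: list
    tree: Phylogeny
    spec: PopulationSpec
    control_points: ControlPointSet = None
    scheme: LandmarkScheme = None

    @property
    def specimen_ids(self) -> list:
        return [m.specimen_id for m in self.meshes]


# ---------------------------------------------------------------------------
# Base geometry


def generate_base_mesh(radius: float, subdivision_level: int) -> TriangleMesh:
    """A closed, outward-oriented icosphere centred at the origin."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ico = _trimesh.creation.icosphere(subdivisions=subdivision_level, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces), "base")


# ---------------------------------------------------------------------------
# Phylogeny


def generate_phylogeny(n_tips: int, seed: int, labels: list | None = None) -> Phylogeny:
    """A rooted ultrametric binary tree sampled from a pure-birth process,
    rescaled to unit root-to-tip depth; identical seed gives an identical
    Newick string."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [{"time": 0.0, "children": []}]
    active = [nodes[0]]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active[k]
        parent["time"] = t
        kids = [{"time": None, "children": []}, {"time": None, "children": []}]
        parent["children"] = kids
        active[k : k + 1] = kids
    t += rng.exponential(1.0 / n_tips)
    for leaf in active:
        leaf["time"] = t
    root = nodes[0]
    depth = t - root["time"]

    if labels is None:
        labels = [f"specimen_{i:03d}" for i in range(n_tips)]
    counter = iter(range(n_tips))

    def newick(node):
        if not node["children"]:
            return labels[next(counter)], node["time"]
        parts = []
        for child in node["children"]:
            s, ct = newick(child)
            parts.append(f"{s}:{(ct - node['time']) / depth!r}")
        return "(" + ",".join(parts) + ")", node["time"]

    s, _ = newick(root)
    tree = dendropy.Tree.get(data=s + ";", schema="newick", preserve_underscores=True)
    return Phylogeny(tree)


def clade_groups(phy: Phylogeny, n_groups: int = 2) -> dict:
    """Assign each tip a group by clade membership: starting from the root
    split, the largest clade is subdivided until ``n_groups`` clades exist."""
    clades = [set(phy.tip_labels)]
    node_of = {frozenset(phy.tip_labels): phy.tree.seed_node}
    while len(clades) < n_groups:
        clades.sort(key=len, reverse=True)
        big = clades.pop(0)
        node = node_of[frozenset(big)]
        children = node.child_nodes()
        if len(children) < 2:
            raise ValueError("cannot split further")
        for ch in children:
            tips = {leaf.taxon.label for leaf in ch.leaf_iter()}
            clades.append(tips)
            node_of[frozenset(tips)] = ch
    clades.sort(key=lambda c: min(c))
    out = {}
    for g, clade in enumerate(clades):
        for tip in clade:
            out[tip] = f"group_{g}"
    return out


# ---------------------------------------------------------------------------
# Ground-truth momenta


def stretch_pattern(control_points: ControlPointSet, radius: float, sigma: float, axis: int = 0) -> np.ndarray:
    """Momenta proportional to each control point's signed coordinate along
    the stretch axis, normalised so a unit coefficient gives an initial
    velocity equal to ``radius`` at the positive pole (a smooth elongation)."""
    q = control_points.positions
    M = np.zeros_like(q)
    M[:, axis] = q[:, axis]
    pole = np.zeros(3)
    pole[axis] = radius
    v = velocity_field(pole, q, M, sigma)[0, axis]
    if v <= 0:
        raise ValueError("degenerate stretch pattern")
    return M * (radius / v)


def simulate_population_momenta(
    spec: PopulationSpec,
    tree: Phylogeny,
    control_points: ControlPointSet,
    stretch: np.ndarray | None = None,
):
    """Per-specimen momenta: elongation + Brownian clade structure + noise.

    momenta[i] = a_i * M_stretch + BM_i + eps_i with a_i ~ N(0, elongation_sd^2),
    BM evolving on the tree with per-coordinate rate ``bm_rate`` and
    eps iid N(0, individual_noise_sd^2) per momentum coordinate.
    Returns (momenta, elongation_coefficients).
    """
    n = spec.n_specimens
    if tree.n_tips != n:
        raise ValueError("tree tip count must equal n_specimens")
    p = control_points.n_points
    if stretch is None:
        stretch = stretch_pattern(control_points, spec.base_radius, spec.kernel_width_true)
    if stretch.shape != (p, 3):
        raise ValueError("stretch pattern does not match control points")
    ss = np.random.SeedSequence([spec.seed, 0xA7])
    rng_elong, rng_bm, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]
    coeffs = rng_elong.normal(0.0, spec.elongation_sd, size=n)
    momenta = coeffs[:, None, None] * stretch[None, :, :]
    if spec.bm_rate > 0:
        order = tree.tip_labels
        C = phylo_covariance(tree, tip_order=order)
        L = np.linalg.cholesky(C)
        Z = rng_bm.standard_normal((n, 3 * p))
        bm = math.sqrt(spec.bm_rate) * (L @ Z)
        momenta += bm.reshape(n, p, 3)
    if spec.individual_noise_sd > 0:
        momenta += rng_noise.normal(0.0, spec.individual_noise_sd, size=(n, p, 3))
    return momenta, coeffs


# ---------------------------------------------------------------------------
# Landmark scheme on the template


def build_landmark_scheme(
    base: TriangleMesh, n_fixed: int = 30, n_curves: int = 4, curve_len: int = 6
) -> LandmarkScheme:
    """A deterministic landmark scheme on base-mesh vertices.

    Fixed landmarks by farthest-point sampling over the vertex set; curve
    semilandmarks as evenly subsampled shortest edge-graph paths between
    pairs of fixed landmarks (path interiors only, so no point is reused).
    """
    V = base.vertices
    fixed = [0]
    d = np.linalg.norm(V - V[0], axis=1)
    while len(fixed) < n_fixed:
        j = int(np.argmax(d))
        fixed.append(j)
        d = np.minimum(d, np.linalg.norm(V - V[j], axis=1))
    edges = np.vstack([base.faces[:, [0, 1]], base.faces[:, [1, 2]], base.faces[:, [2, 0]]])
    w = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
    graph = coo_matrix((np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
                       shape=(len(V), len(V)))
    used = set(fixed)
    indices = list(fixed)
    roles = ["fixed"] * n_fixed
    curves = []
    for c in range(n_curves):
        # Connect the first fixed-landmark pair (scanning sources in order,
        # targets farthest-first) whose shortest path has enough unused
        # interior vertices.
        interior = None
        for a in fixed[c:] + fixed[:c]:
            dist, pred = dijkstra(graph, indices=a, return_predecessors=True)
            for b in sorted(fixed, key=lambda v: -dist[v]):
                if b == a:
                    continue
                path = [b]
                while path[-1] != a:
                    path.append(int(pred[path[-1]]))
                cand = [v for v in path[::-1][1:-1] if v not in used]
                if len(cand) >= curve_len:
                    interior = cand
                    break
            if interior is not None:
                break
        if interior is None:
            raise MeshTopologyError("mesh too coarse for the landmark scheme")
        pick = np.linspace(0, len(interior) - 1, curve_len).round().astype(int)
        pick = sorted(set(pick.tolist()))
        chosen = [interior[i] for i in pick]
        start = len(indices)
        curves.append(list(range(start, start + len(chosen))))
        indices.extend(chosen)
        roles.extend([f"curve:{c}"] * len(chosen))
        used.update(chosen)
    return LandmarkScheme(np.array(indices), roles, curves)


# ---------------------------------------------------------------------------
# Specimen synthesis


def synthesize_specimen(
    base: TriangleMesh,
    control_points: ControlPointSet,
    momenta: np.ndarray,
    kernel_width_true: float,
    scheme: LandmarkScheme | None = None,
    n_steps: int = 10,
    specimen_id: str = "",
):
    """Deform the base mesh by geodesic shooting; landmark positions are the
    tracked vertices after the same flow (exactly homologous)."""
    momenta = np.asarray(momenta, dtype=float)
    if momenta.shape != (control_points.n_points, 3):
        raise ValueError("momenta shape must be (n_control_points, 3)")
    if not np.all(np.isfinite(momenta)):
        raise ValueError("momenta must be finite")
    traj = geodesic_shoot(control_points, momenta, kernel_width_true, n_steps=n_steps)
    verts = flow_points(base.vertices, traj)
    mesh = TriangleMesh(verts, base.faces.copy(), specimen_id)
    lm = None
    if scheme is not None:
        lm = LandmarkConfig(
            verts[scheme.vertex_indices], list(scheme.roles), [list(c) for c in scheme.curves], specimen_id
        )
    return mesh, lm


def introduce_modality_artifact(
    mesh: TriangleMesh, cap_center_vertex: int, cap_radius: float
) -> TriangleMesh:
    """Remove all faces whose centroid lies within ``cap_radius`` of the cap
    centre vertex, producing an open surface (the mixed-modality artifact)."""
    if cap_radius <= 0:
        raise ValueError("cap_radius must be positive")
    centre = mesh.vertices[int(cap_center_vertex)]
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    keep = np.linalg.norm(centroids - centre, axis=1) > cap_radius
    if not np.any(keep):
        raise MeshTopologyError("cap removes all faces")
    out = mesh.copy()
    out.faces = mesh.faces[keep]
    return out


# ---------------------------------------------------------------------------
# Study orchestration


def build_study(
    spec: PopulationSpec,
    out_dir=None,
    cap_radius: float | None = None,
    n_caps: int = 12,
    vertex_jitter_sd: float = 0.0,
    random_groups: bool = False,
    n_steps: int = 10,
) -> SyntheticStudy:
    """Generate the full synthetic study and optionally write it to disk.

    Writes ``specimen_###.ply``, ``landmarks_###.csv``, ``tree.nwk`` and
    ``metadata.csv``; all text output is byte-deterministic for a fixed
    seed.  ``floor(open_fraction * n)`` specimens, chosen by a seeded draw,
    become "open": ``n_caps`` shallow patches of radius ``cap_radius``
    (default a quarter of the base radius) are removed at fixed,
    farthest-point-sampled surface locations shared by all open specimens.
    This emulates CT-derived meshes, which lack many distributed openings
    (foramina, fissures, endocranial walls) amounting to a substantial
    fraction of the total surface, while each individual opening is shallow.
    """
    n = spec.n_specimens
    base = generate_base_mesh(spec.base_radius, spec.subdivision_level)
    cps = init_control_points(base, spec.kernel_width_true)
    # Scale the landmark scheme down on coarse meshes; it stays identical
    # across specimens either way.
    if base.n_vertices >= 160:
        scheme = build_landmark_scheme(base)
    else:
        scheme = build_landmark_scheme(
            base, n_fixed=min(12, base.n_vertices // 4), n_curves=2, curve_len=4
        )
    ss = np.random.SeedSequence([spec.seed, 0x51])
    rng_tree, rng_modality, rng_groups, rng_jitter = [np.random.default_rng(s) for s in ss.spawn(4)]
    tree = generate_phylogeny(n, seed=int(rng_tree.integers(2**31)))
    momenta, coeffs = simulate_population_momenta(spec, tree, cps)
    ids = tree.tip_labels  # specimen_000 ... in tree order
    order = np.argsort(ids)
    # Momenta rows follow tree tip order; reindex everything to sorted IDs.
    ids_sorted = [ids[i] for i in order]
    momenta = momenta[order]
    cap_vertices = _cap_centres(base, n_caps)
    if cap_radius is None:
        cap_radius = 0.25 * spec.base_radius
    n_open = int(math.floor(spec.open_fraction * n))
    # Seeded stratified draw, blocked on the elongation coefficient: one
    # specimen per block becomes open, so the modality split cannot be
    # confounded with the dominant biological axis by sampling accident.
    open_set = set()
    if n_open > 0:
        coeff_sorted = np.argsort(coeffs[order])
        for stratum in np.array_split(coeff_sorted, n_open):
            open_set.add(int(stratum[rng_modality.integers(len(stratum))]))
    if random_groups:
        draws = rng_groups.integers(spec.n_groups, size=n)
        groups_map = {i: f"group_{draws[k]}" for k, i in enumerate(ids_sorted)}
    else:
        groups_map = clade_groups(tree, spec.n_groups)
    meshes, lms, modality = [], [], []
    for i, sid in enumerate(ids_sorted):
        mesh, lm = synthesize_specimen(
            base, cps, momenta[i], spec.kernel_width_true, scheme, n_steps=n_steps, specimen_id=sid
        )
        if vertex_jitter_sd > 0:
            mesh.vertices = mesh.vertices + rng_jitter.normal(0.0, vertex_jitter_sd, mesh.vertices.shape)
        if i in open_set:
            for cv in cap_vertices:
                mesh = introduce_modality_artifact(mesh, cv, cap_radius)
            modality.append("open")
        else:
            modality.append("closed")
        meshes.append(mesh)
        lms.append(lm)
    study = SyntheticStudy(
        meshes=meshes,
        landmarks=lms,
        true_momenta=momenta,
        elongation_coefficients=coeffs[order],
        modality_labels=modality,
        group_labels=[groups_map[sid] for sid in ids_sorted],
        tree=tree,
        spec=spec,
        control_points=cps,
        scheme=scheme,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _cap_centres(base: TriangleMesh, n_caps: int) -> list:
    """Deterministic, well-spread cap centres: farthest-point sampling over
    the base vertices starting from the +z pole."""
    V = base.vertices
    centres = [int(np.argmax(V[:, 2]))]
    d = np.linalg.norm(V - V[centres[0]], axis=1)
    while len(centres) < n_caps:
        j = int(np.argmax(d))
        centres.append(j)
        d = np.minimum(d, np.linalg.norm(V - V[j], axis=1))
    return centres


def _write_study(study: SyntheticStudy, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, (mesh, lm) in enumerate(zip(study.meshes, study.landmarks)):
        write_mesh(mesh, out_dir / f"specimen_{i:03d}.ply")
        write_landmarks(lm, out_dir / f"landmarks_{i:03d}.csv")
    with open(out_dir / "tree.nwk", "w") as fh:
        fh.write(study.tree.newick() + "\n")
    with open(out_dir / "metadata.csv", "w") as fh:
        fh.write("specimen_id,modality,group,elongation_coefficient\n")
        for sid, mod, grp, a in zip(
            study.specimen_ids, study.modality_labels, study.group_labels, study.elongation_coefficients
        ):
            fh.write(f"{sid},{mod},{grp},{a!r}\n")
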