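"""Landmark-free deterministic atlas estimation.

The deformation model is the control-point LDDMM parameterisation: a set of
control points q and, per specimen, momentum vectors mu generate a smooth
time-varying velocity field

    X(x) = sum_i K_sigma(x, q_i) mu_i,      K_sigma(x, y) = exp(-|x - y|^2 / sigma^2),

whose Hamiltonian geodesic flow deforms the template mesh onto each
specimen.  Template-to-specimen residuals are measured with kernel current
or varifold distances on oriented face sets, so no point correspondence is
ever required.  Atlas estimation minimises

    f(T, q, mu) = sum_i [ d^2(Phi_{q,mu_i}(T), C_i) / (2 s_n^2) + (1/2) mu_i' K(q,q) mu_i ]

by gradient descent on the template vertices, the control points and all
momenta jointly, with gradients obtained by hand-derived adjoints of the
discretised forward computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AtlasDivergenceError
from .mesh import OrientedFaceSet, TriangleMesh, oriented_face_set

__all__ = [
    "KernelSpec",
    "ControlPointSet",
    "MomentaField",
    "AtlasConfig",
    "AtlasModel",
    "Trajectory",
    "gaussian_kernel",
    "init_control_points",
    "velocity_field",
    "hamiltonian",
    "geodesic_shoot",
    "flow_points",
    "flow_mesh",
    "mesh_attachment_distance",
    "atlas_loss",
    "atlas_loss_gradients",
    "estimate_atlas",
]


@dataclass
class KernelSpec:
    """Deformation kernel width ``sigma`` and data-attachment width ``sigma_w`` (mm)."""

    sigma: float
    sigma_w: float

    def __post_init__(self):
        if self.sigma <= 0 or self.sigma_w <= 0:
            raise ValueError("kernel widths must be positive")


@dataclass
class ControlPointSet:
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.positions)


@dataclass
class MomentaField:
    """Per-specimen momenta, shape (n_specimens, n_control_points, 3)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("momenta must have shape (n, p, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("momenta must be finite")


@dataclass
class AtlasConfig:
    max_iter: int = 150
    step: float = 0.01
    n_steps: int = 10
    integrator: str = "rk2"
    noise_sigma: float = 10.0
    attachment: str = "varifold"
    optimize_control_points: bool = True
    optimize_template: bool = True
    tol: float = 1e-6
    verbose: bool = False


@dataclass
class AtlasModel:
    template: TriangleMesh
    control_points: ControlPointSet
    momenta: MomentaField
    kernel: KernelSpec
    noise_sigma: float = 10.0
    attachment: str = "varifold"
    loss_trace: list = field(default_factory=list)


@dataclass
class Trajectory:
    """Discretised geodesic: states (q_t, mu_t) at t = 0, h, ..., 1."""

    states: list
    sigma: float
    integrator: str

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1


# ---------------------------------------------------------------------------
# Kernel primitives


def gaussian_kernel(x, y, sigma: float) -> float:
    """K_sigma(x, y) = exp(-|x - y|^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.exp(-np.dot(d, d) / sigma**2))


def _kmat(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(a, b, "sqeuclidean") / sigma**2)


def init_control_points(
    template: TriangleMesh, sigma: float, padding: float | None = None
) -> ControlPointSet:
    """Regular grid at spacing ``sigma`` over the padded template bounding box.

    ``padding`` defaults to ``sigma / 2`` per side; node count per axis is
    ``ceil(padded_extent / sigma) + 1`` and the grid is centred on the box.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if padding is None:
        padding = sigma / 2.0
    lo, hi = template.bounds()
    lo, hi = lo - padding, hi + padding
    extent = hi - lo
    counts = np.ceil(extent / sigma).astype(int) + 1
    axes = []
    for k in range(3):
        span = (counts[k] - 1) * sigma
        start = 0.5 * (lo[k] + hi[k]) - span / 2.0
        axes.append(start + sigma * np.arange(counts[k]))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return ControlPointSet(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))


def velocity_field(x, q, mu, sigma: float) -> np.ndarray:
    """Evaluate X(x) = sum_i K_sigma(x, q_i) mu_i at points x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    qp = q.positions if isinstance(q, ControlPointSet) else np.asarray(q, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return _kmat(x, qp, sigma) @ mu


def _vel(x: np.ndarray, q: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    return _kmat(x, q, sigma) @ mu


def _vel_vjp(x, q, mu, sigma, vbar):
    """VJP of ``_vel`` with respect to (x, q, mu).

    All pairwise-difference contractions are decomposed into matrix products
    (sum_j W_ij (x_i - q_j) = rowsum(W) x_i - W q), so no (n, p, 3) array is
    ever materialised.
    """
    K = _kmat(x, q, sigma)
    mubar = K.T @ vbar
    T = K * (vbar @ mu.T)  # T_ij = K_ij (vbar_i . mu_j)
    c = 2.0 / sigma**2
    xbar = -c * (T.sum(axis=1)[:, None] * x - T @ q)
    qbar = c * (T.T @ x - T.sum(axis=0)[:, None] * q)
    return xbar, qbar, mubar


def _mdot(q: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    """mu_dot_i = (2/sigma^2) sum_j K_ij (mu_i . mu_j) (q_i - q_j)."""
    Ks = _kmat(q, q, sigma) * (mu @ mu.T)
    return (2.0 / sigma**2) * (Ks.sum(axis=1)[:, None] * q - Ks @ q)


def _mdot_vjp(q, mu, sigma, wbar):
    K = _kmat(q, q, sigma)
    s = mu @ mu.T
    c = 2.0 / sigma**2
    # wd_ij = wbar_i . (q_i - q_j)
    wd = np.einsum("ik,ik->i", wbar, q)[:, None] - wbar @ q.T
    # mu path: Sbar_ij = c K_ij wd_ij ; mubar = (Sbar + Sbar') mu
    Sbar = c * K * wd
    mubar = (Sbar + Sbar.T) @ mu
    # q path through d: dbar_ij = c K_ij s_ij wbar_i
    td = c * K * s
    qbar = wbar * td.sum(axis=1)[:, None]
    qbar -= td.T @ wbar
    # q path through K: P_ij = -c^2 K_ij s_ij wd_ij
    P = -(c**2) * K * s * wd
    qbar += P.sum(axis=1)[:, None] * q - P @ q
    qbar -= P.T @ q - P.sum(axis=0)[:, None] * q
    return qbar, mubar


def hamiltonian(q, mu, sigma: float) -> float:
    """H = (1/2) sum_ij K(q_i, q_j) mu_i . mu_j (the deformation kinetic energy)."""
    qp = q.positions if isinstance(q, ControlPointSet) else np.asarray(q, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return 0.5 * float(np.sum(_kmat(qp, qp, sigma) * (mu @ mu.T)))


# ---------------------------------------------------------------------------
# Geodesic shooting and flow


def _joint_rhs(q, mu, x, sigma):
    return _vel(q, q, mu, sigma), _mdot(q, mu, sigma), _vel(x, q, mu, sigma)


def _integrate(q0, mu0, x0, sigma, n_steps, integrator):
    """Forward integration of the joint (q, mu, x) system; returns all step states."""
    h = 1.0 / n_steps
    states = [(q0.copy(), mu0.copy(), x0.copy())]
    q, mu, x = q0.copy(), mu0.copy(), x0.copy()
    for _ in range(n_steps):
        dq, dmu, dx = _joint_rhs(q, mu, x, sigma)
        if integrator == "euler":
            q, mu, x = q + h * dq, mu + h * dmu, x + h * dx
        elif integrator == "rk2":
            qm, mum, xm = q + 0.5 * h * dq, mu + 0.5 * h * dmu, x + 0.5 * h * dx
            dq2, dmu2, dx2 = _joint_rhs(qm, mum, xm, sigma)
            q, mu, x = q + h * dq2, mu + h * dmu2, x + h * dx2
        else:
            raise ValueError(f"unknown integrator: {integrator}")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(x))):
            raise FloatingPointError("non-finite state during integration")
        states.append((q.copy(), mu.copy(), x.copy()))
    return states


def _rhs_vjp(q, mu, x, sigma, qbar_c, mubar_c, xbar_c):
    """VJP of ``_joint_rhs`` at (q, mu, x) with output cotangents."""
    qbar = np.zeros_like(q)
    mubar = np.zeros_like(mu)
    xbar = np.zeros_like(x)
    if qbar_c is not None and np.any(qbar_c):
        xb, qb, mb = _vel_vjp(q, q, mu, sigma, qbar_c)
        qbar += xb + qb
        mubar += mb
    if mubar_c is not None and np.any(mubar_c):
        qb, mb = _mdot_vjp(q, mu, sigma, mubar_c)
        qbar += qb
        mubar += mb
    if xbar_c is not None and np.any(xbar_c):
        xb, qb, mb = _vel_vjp(x, q, mu, sigma, xbar_c)
        xbar += xb
        qbar += qb
        mubar += mb
    return qbar, mubar, xbar


def _integrate_vjp(states, sigma, integrator, qbar, mubar, xbar):
    """Backpropagate cotangents on the final state to the initial state."""
    n_steps = len(states) - 1
    h = 1.0 / n_steps
    for t in range(n_steps - 1, -1, -1):
        q, mu, x = states[t]
        if integrator == "euler":
            gq, gm, gx = _rhs_vjp(q, mu, x, sigma, h * qbar, h * mubar, h * xbar)
            qbar, mubar, xbar = qbar + gq, mubar + gm, xbar + gx
        else:  # rk2 midpoint
            dq, dmu, dx = _joint_rhs(q, mu, x, sigma)
            qm, mum, xm = q + 0.5 * h * dq, mu + 0.5 * h * dmu, x + 0.5 * h * dx
            g1q, g1m, g1x = _rhs_vjp(qm, mum, xm, sigma, h * qbar, h * mubar, h * xbar)
            g2q, g2m, g2x = _rhs_vjp(
                q, mu, x, sigma, 0.5 * h * g1q, 0.5 * h * g1m, 0.5 * h * g1x
            )
            qbar = qbar + g1q + g2q
            mubar = mubar + g1m + g2m
            xbar = xbar + g1x + g2x
    return qbar, mubar, xbar


def geodesic_shoot(
    q0, mu0, sigma: float, n_steps: int = 10, integrator: str = "rk2"
) -> Trajectory:
    """Integrate the Hamiltonian system q_dot = K(q,q) mu,
    mu_dot = -(1/2) grad_q (K(q,q) mu' mu) over t in [0, 1]."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    q0 = q0.positions if isinstance(q0, ControlPointSet) else np.asarray(q0, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    states = _integrate(q0, mu0, np.zeros((0, 3)), sigma, n_steps, integrator)
    return Trajectory(
        states=[(q, mu) for q, mu, _ in states], sigma=sigma, integrator=integrator
    )


def flow_points(points: np.ndarray, trajectory: Trajectory) -> np.ndarray:
    """Advect points through x_dot(t) = sum_i K(x, q_i(t)) mu_i(t) with the
    trajectory's own integrator and step count."""
    x = np.asarray(points, dtype=float).copy()
    sigma = trajectory.sigma
    h = 1.0 / trajectory.n_steps
    for t in range(trajectory.n_steps):
        q, mu = trajectory.states[t]
        dx = _vel(x, q, mu, sigma)
        if trajectory.integrator == "euler":
            x = x + h * dx
        else:
            dq, dmu, _ = _joint_rhs(q, mu, np.zeros((0, 3)), sigma)
            qm, mum = q + 0.5 * h * dq, mu + 0.5 * h * dmu
            xm = x + 0.5 * h * dx
            x = x + h * _vel(xm, qm, mum, sigma)
    return x


def flow_mesh(mesh: TriangleMesh, trajectory: Trajectory, sigma: float | None = None) -> TriangleMesh:
    """Deform a mesh by advecting its vertices along a shot geodesic."""
    if sigma is not None and abs(sigma - trajectory.sigma) > 1e-12:
        raise ValueError("sigma does not match the trajectory's kernel width")
    out = mesh.copy()
    out.vertices = flow_points(mesh.vertices, trajectory)
    return out


# ---------------------------------------------------------------------------
# Current / varifold attachment


def _inner_current(ca, na, cb, nb, sigma_w):
    K = _kmat(ca, cb, sigma_w)
    return float(np.sum(K * (na @ nb.T)))


def _inner_varifold(ca, na, cb, nb, sigma_w):
    K = _kmat(ca, cb, sigma_w)
    la = np.linalg.norm(na, axis=1)
    lb = np.linalg.norm(nb, axis=1)
    dot = na @ nb.T
    with np.errstate(divide="ignore", invalid="ignore"):
        h = dot**2 / np.outer(la, lb)
    h[~np.isfinite(h)] = 0.0
    return float(np.sum(K * h))


def mesh_attachment_distance(
    a: OrientedFaceSet, b: OrientedFaceSet, sigma_w: float, mode: str = "varifold"
) -> float:
    """Squared kernel distance between two oriented face sets.

    d^2 = <A,A> - 2 <A,B> + <B,B> with the current inner product
    K_w(c_p, c_q) n_p . n_q, or the varifold one
    K_w(c_p, c_q) (n_p . n_q)^2 / (|n_p| |n_q|), which ignores orientation
    sign.  Zero-area faces contribute nothing in either mode.
    """
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    if len(a.centres) == 0 or len(b.centres) == 0:
        raise ValueError("face sets must be non-empty")
    inner = {"current": _inner_current, "varifold": _inner_varifold}[mode]
    d2 = (
        inner(a.centres, a.normals, a.centres, a.normals, sigma_w)
        - 2.0 * inner(a.centres, a.normals, b.centres, b.normals, sigma_w)
        + inner(b.centres, b.normals, b.centres, b.normals, sigma_w)
    )
    return max(d2, 0.0)


def _faceset_arrays(verts, faces):
    tri = verts[faces]
    centres = tri.mean(axis=1)
    normals = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return centres, normals


def _attachment_grad_cn(ca, na, cb, nb, sigma_w, mode):
    """d^2 against fixed target (cb, nb) and its gradient wrt (ca, na).

    The constant <B,B> term is omitted from the returned value (the caller
    adds it); it has zero gradient.
    """
    c2 = 2.0 / sigma_w**2

    def pair(cx, nx, cy, ny, sym):
        K = np.exp(-cdist(cx, cy, "sqeuclidean") / sigma_w**2)
        if mode == "current":
            dot = nx @ ny.T
            val = float(np.sum(K * dot))
            gn = (2.0 if sym else 1.0) * (K @ ny)
            W = K * dot
        else:
            lx = np.linalg.norm(nx, axis=1)
            ly = np.linalg.norm(ny, axis=1)
            dot = nx @ ny.T
            with np.errstate(divide="ignore", invalid="ignore"):
                denom = np.outer(lx, ly)
                h = np.where(denom > 0, dot**2 / denom, 0.0)
                # dh/dnx = 2 dot ny / denom - h nx / lx^2
                w1 = np.where(denom > 0, 2.0 * dot / denom, 0.0)
            val = float(np.sum(K * h))
            gn = (K * w1) @ ny
            with np.errstate(divide="ignore", invalid="ignore"):
                ssum = np.where(lx > 0, (K * h).sum(axis=1) / lx**2, 0.0)
            gn -= ssum[:, None] * nx
            if sym:
                gn *= 2.0
            W = K * h
        gc = -c2 * (
            W.sum(axis=1)[:, None] * cx - W @ cy
        )  # sum_j W_ij (cx_i - cy_j), kernel derivative
        if sym:
            gc *= 2.0
        return val, gc, gn

    vaa, gc_aa, gn_aa = pair(ca, na, ca, na, sym=True)
    vab, gc_ab, gn_ab = pair(ca, na, cb, nb, sym=False)
    val = vaa - 2.0 * vab
    gc = gc_aa - 2.0 * gc_ab
    gn = gn_aa - 2.0 * gn_ab
    return val, gc, gn


def _attachment_grad_verts(verts, faces, target: OrientedFaceSet, sigma_w, mode, bb):
    """d^2(mesh(verts, faces), target) and its gradient wrt verts.

    ``bb`` is the precomputed <B,B> self term of the target.
    """
    ca, na = _faceset_arrays(verts, faces)
    val, gc, gn = _attachment_grad_cn(ca, na, target.centres, target.normals, sigma_w, mode)
    val += bb
    grad = np.zeros_like(verts)
    i, j, k = faces[:, 0], faces[:, 1], faces[:, 2]
    third = gc / 3.0
    np.add.at(grad, i, third)
    np.add.at(grad, j, third)
    np.add.at(grad, k, third)
    e1 = verts[j] - verts[i]
    e2 = verts[k] - verts[i]
    ge1 = 0.5 * np.cross(e2, gn)
    ge2 = 0.5 * np.cross(gn, e1)
    np.add.at(grad, i, -ge1 - ge2)
    np.add.at(grad, j, ge1)
    np.add.at(grad, k, ge2)
    return val, grad


def _self_inner(fs: OrientedFaceSet, sigma_w, mode):
    inner = {"current": _inner_current, "varifold": _inner_varifold}[mode]
    return inner(fs.centres, fs.normals, fs.centres, fs.normals, sigma_w)


# ---------------------------------------------------------------------------
# Atlas loss and estimation


def atlas_loss(model: AtlasModel, specimens: list[TriangleMesh], config: AtlasConfig | None = None):
    """Total loss with per-specimen data and regularity terms.

    data_i = d^2(flowed template, C_i) / (2 noise_sigma^2);
    reg_i = (1/2) mu_i' K(q, q) mu_i (initial kinetic energy).
    """
    cfg = config or AtlasConfig(
        noise_sigma=model.noise_sigma, attachment=model.attachment
    )
    q0 = model.control_points.positions
    sigma = model.kernel.sigma
    data_terms, reg_terms = [], []
    for i, spec in enumerate(specimens):
        mu = model.momenta.values[i]
        states = _integrate(
            q0, mu, model.template.vertices, sigma, cfg.n_steps, cfg.integrator
        )
        ca, na = _faceset_arrays(states[-1][2], model.template.faces)
        tgt = oriented_face_set(spec)
        inner = {"current": _inner_current, "varifold": _inner_varifold}[model.attachment]
        d2 = (
            inner(ca, na, ca, na, model.kernel.sigma_w)
            - 2.0 * inner(ca, na, tgt.centres, tgt.normals, model.kernel.sigma_w)
            + _self_inner(tgt, model.kernel.sigma_w, model.attachment)
        )
        data_terms.append(max(d2, 0.0) / (2.0 * model.noise_sigma**2))
        reg_terms.append(hamiltonian(q0, mu, sigma))
    data_terms = np.array(data_terms)
    reg_terms = np.array(reg_terms)
    return float(data_terms.sum() + reg_terms.sum()), data_terms, reg_terms


def _loss_and_grad(
    template_verts,
    faces,
    q0,
    mu_all,
    targets,
    bb_terms,
    kernel: KernelSpec,
    cfg: AtlasConfig,
    with_grad: bool = True,
):
    n = len(targets)
    inv2s = 1.0 / (2.0 * cfg.noise_sigma**2)
    data_terms = np.zeros(n)
    reg_terms = np.zeros(n)
    gT = np.zeros_like(template_verts)
    gq = np.zeros_like(q0)
    gmu = np.zeros_like(mu_all)
    for i in range(n):
        mu = mu_all[i]
        states = _integrate(q0, mu, template_verts, kernel.sigma, cfg.n_steps, cfg.integrator)
        xT = states[-1][2]
        if with_grad:
            d2, gx = _attachment_grad_verts(
                xT, faces, targets[i], kernel.sigma_w, cfg.attachment, bb_terms[i]
            )
            qb, mb, xb = _integrate_vjp(
                states,
                kernel.sigma,
                cfg.integrator,
                np.zeros_like(q0),
                np.zeros_like(mu),
                gx * inv2s,
            )
            gT += xb
            gq += qb
            gmu[i] = mb
            # regularity gradients: grad_mu H = K mu ; grad_q H = -mu_dot
            gmu[i] += _vel(q0, q0, mu, kernel.sigma)
            gq -= _mdot(q0, mu, kernel.sigma)
        else:
            ca, na = _faceset_arrays(xT, faces)
            inner = {"current": _inner_current, "varifold": _inner_varifold}[cfg.attachment]
            d2 = (
                inner(ca, na, ca, na, kernel.sigma_w)
                - 2.0 * inner(ca, na, targets[i].centres, targets[i].normals, kernel.sigma_w)
                + bb_terms[i]
            )
        data_terms[i] = max(d2, 0.0) * inv2s
        reg_terms[i] = hamiltonian(q0, mu, kernel.sigma)
    total = float(data_terms.sum() + reg_terms.sum())
    return total, data_terms, reg_terms, gT, gq, gmu


def atlas_loss_gradients(model: AtlasModel, specimens: list[TriangleMesh], config: AtlasConfig | None = None):
    """Gradients of the total atlas loss wrt template vertices, control points
    and momenta (for checking against finite differences and for fitting)."""
    cfg = config or AtlasConfig(noise_sigma=model.noise_sigma, attachment=model.attachment)
    cfg.noise_sigma = model.noise_sigma
    cfg.attachment = model.attachment
    targets = [oriented_face_set(s) for s in specimens]
    bb = [_self_inner(t, model.kernel.sigma_w, model.attachment) for t in targets]
    total, data_terms, reg_terms, gT, gq, gmu = _loss_and_grad(
        model.template.vertices,
        model.template.faces,
        model.control_points.positions,
        model.momenta.values,
        targets,
        bb,
        model.kernel,
        cfg,
    )
    return total, {"template": gT, "control_points": gq, "momenta": gmu}


def estimate_atlas(
    specimens: list[TriangleMesh],
    initial_template: TriangleMesh,
    kernel: KernelSpec,
    config: AtlasConfig | None = None,
) -> AtlasModel:
    """Fit template, control points and momenta by joint gradient descent.

    Momenta start at zero and control points on the kernel-width grid.  The
    initial step is interpreted as a fraction of the template bounding-box
    diagonal: each parameter block is rescaled by its gradient's initial
    max-norm so the first accepted update moves no coordinate by more than
    ``step * diagonal``.  The step halves whenever a trial increases the
    loss (the step is re-tried) and cautiously doubles after five
    consecutive accepted steps.  The whole procedure is deterministic.
    """
    if len(specimens) < 2:
        raise ValueError("need at least two specimens")
    cfg = config or AtlasConfig()
    T = initial_template.vertices.copy()
    faces = initial_template.faces.copy()
    q = init_control_points(initial_template, kernel.sigma).positions
    mu = np.zeros((len(specimens), len(q), 3))
    targets = [oriented_face_set(s) for s in specimens]
    bb = [_self_inner(t, kernel.sigma_w, cfg.attachment) for t in targets]
    diag = float(np.linalg.norm(T.max(axis=0) - T.min(axis=0)))

    def evaluate(Tv, qv, muv, with_grad):
        return _loss_and_grad(Tv, faces, qv, muv, targets, bb, kernel, cfg, with_grad)

    total, data_terms, reg_terms, gT, gq, gmu = evaluate(T, q, mu, True)
    if not np.isfinite(total):
        raise AtlasDivergenceError(0)
    trace = [total]
    scales = {}
    for name, g in (("T", gT), ("q", gq), ("mu", gmu)):
        gmax = float(np.max(np.abs(g))) if g.size else 0.0
        scales[name] = diag / gmax if gmax > 0 else 1.0

    step = cfg.step
    consec = 0
    for it in range(cfg.max_iter):
        accepted = False
        while step > 1e-14:
            T_new = T - step * scales["T"] * gT if cfg.optimize_template else T
            q_new = q - step * scales["q"] * gq if cfg.optimize_control_points else q
            mu_new = mu - step * scales["mu"] * gmu
            try:
                res = evaluate(T_new, q_new, mu_new, True)
            except FloatingPointError:
                res = (np.nan,) * 6
            new_total = res[0]
            if np.isfinite(new_total) and new_total <= total:
                accepted = True
                break
            step *= 0.5
            consec = 0
        if not accepted:
            break
        prev = total
        total, data_terms, reg_terms, gT, gq, gmu = res
        T, q, mu = T_new, q_new, mu_new
        trace.append(total)
        consec += 1
        if consec >= 5:
            step *= 2.0
            consec = 0
        if cfg.verbose:
            print(f"iter {it + 1}: loss {total:.6g} (data {data_terms.sum():.6g}) step {step:.3g}")
        if abs(prev - total) < cfg.tol * max(abs(prev), 1e-30):
            break

    return AtlasModel(
        template=TriangleMesh(T, faces, initial_template.specimen_id),
        control_points=ControlPointSet(q),
        momenta=MomentaField(mu),
        kernel=kernel,
        noise_sigma=cfg.noise_sigma,
        attachment=cfg.attachment,
        loss_trace=trace,
    )
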