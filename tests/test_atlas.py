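"""Kernel deformation model: shooting, flow, attachment, loss, gradients."""

import numpy as np
import pytest

from morphoatlas.atlas import (
    AtlasConfig,
    AtlasModel,
    ControlPointSet,
    KernelSpec,
    MomentaField,
    atlas_loss,
    atlas_loss_gradients,
    estimate_atlas,
    flow_mesh,
    flow_points,
    gaussian_kernel,
    geodesic_shoot,
    hamiltonian,
    init_control_points,
    mesh_attachment_distance,
    velocity_field,
)
from morphoatlas.mesh import TriangleMesh, oriented_face_set

from .conftest import icosphere


class TestKernel:
    def test_unit_at_zero_distance(self):
        assert gaussian_kernel([1, 2, 3], [1, 2, 3], 5.0) == 1.0

    def test_e_minus_one_at_sigma(self):
        assert gaussian_kernel([0, 0, 0], [2.0, 0, 0], 2.0) == pytest.approx(
            np.exp(-1), rel=1e-12
        )

    def test_symmetry(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=(2, 3))
            assert gaussian_kernel(x, y, 1.7) == pytest.approx(
                gaussian_kernel(y, x, 1.7), rel=1e-15
            )


class TestControlPoints:
    def test_grid_count_no_padding(self):
        box = TriangleMesh(
            [[0, 0, 0], [100, 0, 0], [0, 100, 0], [0, 0, 100], [100, 100, 100]],
            [[0, 1, 2]],
        )
        cps = init_control_points(box, 50.0, padding=0.0)
        assert cps.n_points == 27

    def test_large_sigma_gives_8_corners(self):
        box = TriangleMesh(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 10]], [[0, 1, 2]]
        )
        cps = init_control_points(box, 500.0, padding=0.0)
        assert cps.n_points == 8

    def test_grid_spacing_is_sigma(self, icosahedron):
        cps = init_control_points(icosahedron, 0.8)
        xs = np.unique(cps.positions[:, 0])
        assert np.allclose(np.diff(xs), 0.8)


class TestVelocityField:
    def test_translation_at_control_point(self):
        q = ControlPointSet([[0.0, 0, 0]])
        v = velocity_field([[0.0, 0, 0]], q, [[1.0, 0, 0]], 2.0)
        assert np.allclose(v, [[1, 0, 0]])

    def test_decay_at_sigma(self):
        q = ControlPointSet([[0.0, 0, 0]])
        v = velocity_field([[2.0, 0, 0]], q, [[1.0, 0, 0]], 2.0)
        assert np.allclose(v, [[np.exp(-1), 0, 0]])

    def test_superposition(self, rng):
        q = rng.normal(size=(2, 3))
        mu = rng.normal(size=(2, 3))
        x = rng.normal(size=(5, 3))
        both = velocity_field(x, q, mu, 1.5)
        single = velocity_field(x, q[:1], mu[:1], 1.5) + velocity_field(
            x, q[1:], mu[1:], 1.5
        )
        assert np.allclose(both, single, atol=1e-14)


class TestShooting:
    def test_zero_momenta_fixed_point(self, rng):
        q0 = rng.normal(size=(4, 3))
        traj = geodesic_shoot(q0, np.zeros((4, 3)), 1.0, n_steps=5)
        for q, mu in traj.states:
            assert np.array_equal(q, q0)
            assert np.all(mu == 0)

    @pytest.mark.parametrize("n_steps", [1, 3, 20])
    def test_single_control_point_exact_translation(self, n_steps):
        q0 = np.array([[1.0, -2.0, 0.5]])
        mu0 = np.array([[3.0, 1.0, -2.0]])
        traj = geodesic_shoot(q0, mu0, 2.0, n_steps=n_steps)
        qT, muT = traj.states[-1]
        assert np.abs(qT - (q0 + mu0)).max() <= 1e-10
        assert np.abs(muT - mu0).max() <= 1e-10

    def test_hamiltonian_drift_and_momentum_conservation(self, rng):
        for _ in range(5):
            q0 = rng.normal(size=(5, 3)) * 1.5
            mu0 = rng.normal(size=(5, 3)) * 0.6
            traj = geodesic_shoot(q0, mu0, 1.0, n_steps=20, integrator="rk2")
            H = [hamiltonian(q, mu, 1.0) for q, mu in traj.states]
            assert abs(H[-1] - H[0]) <= 1e-3 * abs(H[0])
            qT, muT = traj.states[-1]
            assert np.abs(muT.sum(axis=0) - mu0.sum(axis=0)).max() <= 1e-6

    def test_rk2_matches_fine_step_reference(self, rng):
        q0 = rng.normal(size=(3, 3))
        mu0 = rng.normal(size=(3, 3)) * 0.5
        coarse = geodesic_shoot(q0, mu0, 1.2, n_steps=20)
        fine = geodesic_shoot(q0, mu0, 1.2, n_steps=200)
        assert np.abs(coarse.states[-1][0] - fine.states[-1][0]).max() <= 1e-3


class TestFlow:
    def test_zero_momenta_identity(self, icosahedron):
        traj = geodesic_shoot(np.zeros((1, 3)), np.zeros((1, 3)), 1.0, n_steps=5)
        out = flow_mesh(icosahedron, traj)
        assert np.array_equal(out.vertices, icosahedron.vertices)
        assert np.array_equal(out.faces, icosahedron.faces)

    def test_vertex_on_control_point_rides_translation(self):
        q0 = np.array([[0.5, 0.5, 0.5]])
        mu0 = np.array([[1.0, -1.0, 2.0]])
        traj = geodesic_shoot(q0, mu0, 3.0, n_steps=50)
        x = flow_points(q0.copy(), traj)
        assert np.abs(x - (q0 + mu0)).max() <= 1e-6

    def test_far_vertex_barely_moves(self):
        # a vertex kept >= 10 sigma from the control point throughout the
        # flow moves by no more than kernel decay plus float round-off
        sigma = 1.0
        q0 = np.array([[0.0, 0, 0]])
        mu0 = np.array([[5.0, 0, 0]])
        traj = geodesic_shoot(q0, mu0, sigma, n_steps=10)
        far = np.array([[0.0, 10.0 * sigma, 0]])
        moved = flow_points(far, traj)
        assert np.linalg.norm(moved - far) <= max(np.exp(-100) * 50.0, 1e-12)


def _brute_force_attachment(a, b, sigma_w, mode):
    total = 0.0
    for ca, na, sa in [(a, a, 1.0), (a, b, -2.0), (b, b, 1.0)]:
        for i in range(len(ca.centres)):
            for j in range(len(na.centres)):
                K = np.exp(
                    -np.sum((ca.centres[i] - na.centres[j]) ** 2) / sigma_w**2
                )
                dot = ca.normals[i] @ na.normals[j]
                if mode == "current":
                    total += sa * K * dot
                else:
                    la = np.linalg.norm(ca.normals[i])
                    lb = np.linalg.norm(na.normals[j])
                    if la > 0 and lb > 0:
                        total += sa * K * dot**2 / (la * lb)
    return total


class TestAttachment:
    @pytest.mark.parametrize("mode", ["current", "varifold"])
    def test_zero_on_identical(self, mode, icosahedron):
        fs = oriented_face_set(icosahedron)
        assert mesh_attachment_distance(fs, fs, 0.7, mode) <= 1e-9

    @pytest.mark.parametrize("mode", ["current", "varifold"])
    def test_symmetry(self, mode, rng):
        a = oriented_face_set(
            TriangleMesh(rng.normal(size=(6, 3)), [[0, 1, 2], [3, 4, 5]])
        )
        b = oriented_face_set(
            TriangleMesh(rng.normal(size=(6, 3)), [[0, 1, 2], [3, 4, 5]])
        )
        d_ab = mesh_attachment_distance(a, b, 1.1, mode)
        d_ba = mesh_attachment_distance(b, a, 1.1, mode)
        assert d_ab == pytest.approx(d_ba, rel=1e-12)

    @pytest.mark.parametrize("mode", ["current", "varifold"])
    def test_matches_double_loop_oracle(self, mode, rng):
        a = oriented_face_set(icosphere(0, 1.0))
        m = icosphere(0, 1.0)
        m.vertices = m.vertices * 1.2 + rng.normal(size=m.vertices.shape) * 0.05
        b = oriented_face_set(m)
        fast = mesh_attachment_distance(a, b, 0.9, mode)
        slow = _brute_force_attachment(a, b, 0.9, mode)
        assert fast == pytest.approx(max(slow, 0.0), abs=1e-12 * max(abs(slow), 1.0))

    def test_varifold_ignores_orientation(self, icosahedron):
        fs = oriented_face_set(icosahedron)
        rev = icosahedron.copy()
        rev.faces = rev.faces[:, ::-1].copy()
        fs_rev = oriented_face_set(rev)
        assert mesh_attachment_distance(fs, fs_rev, 0.7, "varifold") <= 1e-9
        assert mesh_attachment_distance(fs, fs_rev, 0.7, "current") > 1.0


class TestAtlasLoss:
    def _tiny_model(self, rng, noise_sigma=2.0, attachment="varifold"):
        template = icosphere(0, 1.0)
        specs = []
        for _ in range(2):
            m = template.copy()
            m.vertices = m.vertices * 1.1 + rng.normal(size=(12, 3)) * 0.05
            specs.append(m)
        q = ControlPointSet(rng.normal(size=(4, 3)))
        mu = MomentaField(rng.normal(size=(2, 4, 3)) * 0.3)
        kern = KernelSpec(1.0, 0.5)
        model = AtlasModel(template, q, mu, kern, noise_sigma=noise_sigma, attachment=attachment)
        cfg = AtlasConfig(n_steps=5, noise_sigma=noise_sigma, attachment=attachment)
        return model, specs, cfg

    def test_zero_momenta_identical_template_zero_loss(self, icosahedron):
        q = ControlPointSet([[0.0, 0, 0]])
        mu = MomentaField(np.zeros((2, 1, 3)))
        model = AtlasModel(icosahedron, q, mu, KernelSpec(1.0, 0.5))
        total, data, reg = atlas_loss(model, [icosahedron.copy(), icosahedron.copy()])
        assert total <= 1e-9
        assert np.all(reg == 0)

    def test_noise_sigma_scaling(self, rng):
        model, specs, cfg = self._tiny_model(rng)
        _, data1, reg1 = atlas_loss(model, specs, cfg)
        model.noise_sigma = cfg.noise_sigma = 4.0
        _, data2, reg2 = atlas_loss(model, specs, cfg)
        assert np.allclose(data2, data1 / 4.0, rtol=1e-12)
        assert np.allclose(reg2, reg1)

    @pytest.mark.parametrize("attachment", ["varifold", "current"])
    def test_gradients_match_central_finite_differences(self, rng, attachment):
        model, specs, cfg = self._tiny_model(rng, attachment=attachment)
        total, grads = atlas_loss_gradients(model, specs, cfg)
        eps = 1e-6

        def loss_with(Tv=None, qv=None, mv=None):
            m = AtlasModel(
                TriangleMesh(
                    model.template.vertices if Tv is None else Tv, model.template.faces
                ),
                ControlPointSet(model.control_points.positions if qv is None else qv),
                MomentaField(model.momenta.values if mv is None else mv),
                model.kernel,
                noise_sigma=model.noise_sigma,
                attachment=attachment,
            )
            return atlas_loss(m, specs, cfg)[0]

        for name, arr, fn in [
            ("template", model.template.vertices, lambda a: loss_with(Tv=a)),
            ("control_points", model.control_points.positions, lambda a: loss_with(qv=a)),
            ("momenta", model.momenta.values, lambda a: loss_with(mv=a)),
        ]:
            fd = np.zeros_like(arr)
            for idx in np.ndindex(arr.shape):
                up = arr.copy()
                up[idx] += eps
                dn = arr.copy()
                dn[idx] -= eps
                fd[idx] = (fn(up) - fn(dn)) / (2 * eps)
            scale = max(np.abs(fd).max(), 1e-12)
            assert np.abs(grads[name] - fd).max() <= 1e-4 * scale, name


class TestEstimateAtlas:
    def test_identical_specimens_stay_at_zero_deformation(self, rng):
        template = icosphere(1, 1.0)
        specs = [template.copy(), template.copy(), template.copy()]
        kern = KernelSpec(1.0, 0.5)
        cfg = AtlasConfig(max_iter=10, n_steps=5, noise_sigma=1.0)
        model = estimate_atlas(specs, template, kern, cfg)
        assert np.abs(model.momenta.values).max() <= 1e-6
        assert np.abs(model.template.vertices - template.vertices).max() <= 1e-6

    def test_loss_trace_monotone_nonincreasing(self, rng):
        template = icosphere(1, 10.0)
        specs = []
        for k in range(3):
            m = template.copy()
            m.vertices = m.vertices * (1.0 + 0.1 * rng.normal(size=(42, 3)))
            specs.append(m)
        cfg = AtlasConfig(max_iter=8, n_steps=5, noise_sigma=5.0)
        model = estimate_atlas(specs, template, KernelSpec(8.0, 4.0), cfg)
        trace = np.array(model.loss_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-12)

    def test_deterministic(self, rng):
        template = icosphere(1, 10.0)
        specs = []
        for k in range(2):
            m = template.copy()
            m.vertices = m.vertices * (1.0 + 0.05 * rng.normal(size=(42, 3)))
            specs.append(m)
        cfg = AtlasConfig(max_iter=4, n_steps=5, noise_sigma=5.0)
        m1 = estimate_atlas(specs, template, KernelSpec(8.0, 4.0), cfg)
        m2 = estimate_atlas(specs, template, KernelSpec(8.0, 4.0), cfg)
        assert np.array_equal(m1.momenta.values, m2.momenta.values)
        assert m1.loss_trace == m2.loss_trace
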