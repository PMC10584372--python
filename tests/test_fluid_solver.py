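"""Coupling kernel, Stokes solve, and the two dynamics backends."""
from types import SimpleNamespace

import numpy as np
import pytest

import embryomech as em
from embryomech.fluid_solver import (
    CouplingKernel,
    ImmersedBoundaryBackend,
    get_stokes_solver,
    interpolate_velocities,
    solve_stokes,
    spread_forces,
    step_ib,
    step_overdamped,
)
from embryomech.geometry import build_fluid_domain


def _free_space_stokeslet(r, f, mu):
    rn = np.linalg.norm(r, axis=1, keepdims=True)
    return (f / rn + r * (r @ f.T) / rn**3) / (8.0 * np.pi * mu)


@pytest.fixture(scope="module")
def kernel(ball_domain):
    return CouplingKernel(support_radius=2.0 * ball_domain.resolution)


@pytest.fixture(scope="module")
def solid_cloud(rng):
    return rng.uniform(-20.0, 20.0, size=(12, 3))


class TestCouplingKernel:
    def test_partition_of_unity_constant_field(self, ball_domain, kernel, solid_cloud):
        const = np.tile([0.0, 0.0, 1.0], (ball_domain.n_nodes, 1))
        out = interpolate_velocities(const, solid_cloud, ball_domain, kernel)
        np.testing.assert_allclose(out, np.tile([0.0, 0.0, 1.0], (len(out), 1)), atol=1e-12)

    def test_zero_fields_map_to_zero(self, ball_domain, kernel, solid_cloud):
        z = np.zeros((len(solid_cloud), 3))
        assert np.all(spread_forces(solid_cloud, z, ball_domain, kernel) == 0.0)
        zf = np.zeros((ball_domain.n_nodes, 3))
        assert np.all(interpolate_velocities(zf, solid_cloud, ball_domain, kernel) == 0.0)

    def test_force_conservation(self, ball_domain, kernel, solid_cloud, rng):
        f = rng.standard_normal(solid_cloud.shape)
        dens = spread_forces(solid_cloud, f, ball_domain, kernel)
        total = (dens * ball_domain.node_volumes[:, None]).sum(axis=0)
        np.testing.assert_allclose(total, f.sum(axis=0), rtol=1e-10, atol=1e-12)

    def test_opposite_coincident_forces_cancel(self, ball_domain, kernel):
        nodes = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        f = np.array([[1.0, -2.0, 0.5], [-1.0, 2.0, -0.5]])
        dens = spread_forces(nodes, f, ball_domain, kernel)
        np.testing.assert_allclose(dens, 0.0, atol=1e-14)

    def test_interpolation_is_adjoint_of_spreading(self, ball_domain, kernel, solid_cloud, rng):
        f = rng.standard_normal(solid_cloud.shape)
        u = rng.standard_normal((ball_domain.n_nodes, 3))
        dens = spread_forces(solid_cloud, f, ball_domain, kernel)
        lhs = np.sum(dens * ball_domain.node_volumes[:, None] * u)
        rhs = np.sum(f * interpolate_velocities(u, solid_cloud, ball_domain, kernel))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_node_outside_support_rejected(self, ball_domain, kernel):
        far = np.array([[500.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="support"):
            spread_forces(far, np.ones((1, 3)), ball_domain, kernel)


class TestStokesSolver:
    def test_zero_force_zero_velocity(self, ball_domain):
        u = solve_stokes(ball_domain, np.zeros((ball_domain.n_nodes, 3)))
        np.testing.assert_allclose(u, 0.0, atol=1e-14)

    def test_linearity(self, ball_domain, rng):
        dens = rng.standard_normal((ball_domain.n_nodes, 3))
        u1 = solve_stokes(ball_domain, dens)
        u2 = solve_stokes(ball_domain, 2.0 * dens)
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-12, atol=1e-14)

    def test_no_slip_at_shell(self, ball_domain, rng):
        dens = rng.standard_normal((ball_domain.n_nodes, 3))
        u = solve_stokes(ball_domain, dens)
        assert np.abs(u[ball_domain.shell_mask]).max() == 0.0

    def test_near_field_matches_free_space_stokeslet(self, ball_domain):
        solver = get_stokes_solver(ball_domain, eps=0.3)
        ci = int(np.argmin(np.linalg.norm(ball_domain.nodes, axis=1)))
        F = np.zeros((ball_domain.n_nodes, 3))
        F[ci, 0] = 1.0
        centre = ball_domain.nodes[ci]
        rng = np.random.default_rng(7)
        d = rng.standard_normal((40, 3))
        pts = centre + 1.5 * d / np.linalg.norm(d, axis=1, keepdims=True)
        u = solver.velocity_at(pts, F)
        ua = _free_space_stokeslet(pts - centre, np.array([[1.0, 0.0, 0.0]]), solver.mu)
        rel = np.linalg.norm(u - ua, axis=1) / np.linalg.norm(ua, axis=1)
        assert rel.max() < 0.10

    def test_boundary_residual_decreases_with_shell_refinement(self):
        spec = em.EmbryoGeometrySpec(
            long_axis=102.0, short_axis=100.0, n_cells=20,
            height_mid=10.0, height_pole=5.0,
        )
        residuals = []
        for n_shell in (150, 600):
            dom = build_fluid_domain(spec, 12.0, collapse_gap=True, n_shell=n_shell)
            solver = get_stokes_solver(dom, eps=6.0)
            F = np.zeros((dom.n_nodes, 3))
            F[int(np.argmin(np.linalg.norm(dom.nodes, axis=1))), 0] = 1.0
            # held-out points on the shell, between collocation nodes
            rng = np.random.default_rng(5)
            d = rng.standard_normal((200, 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            pts = d * np.array([51.0, 50.0, 50.0])
            u = solver.velocity_at(pts, F)
            residuals.append(np.linalg.norm(u, axis=1).max())
        assert residuals[1] < residuals[0]


class TestBackendSteps:
    @pytest.fixture(scope="class")
    def spring_system(self):
        mesh = SimpleNamespace(
            edges=np.array([[0, 1]]),
            rest_lengths=np.array([24.0]),
            compartment=np.array([0]),
        )
        pos = np.array([[-15.0, 0.0, 0.0], [15.0, 0.0, 0.0]])
        return mesh, pos

    def test_overdamped_displacement(self):
        mesh = SimpleNamespace(
            edges=np.array([[0, 1]]), rest_lengths=np.array([5.0]),
            compartment=np.array([0]),
        )
        pos = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        ext = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        new = step_overdamped(pos, mesh, em.ElasticParams.uniform(0.0), 1.0, 0.1, ext)
        assert new[0, 0] == pytest.approx(0.1)

    def test_overdamped_equilibrium_fixed(self, small_mesh):
        params = em.ElasticParams.uniform(0.05)
        new = step_overdamped(small_mesh.nodes, small_mesh, params, 1.0, 0.5)
        np.testing.assert_array_equal(new, small_mesh.nodes)

    def test_single_spring_closed_form_relaxation(self):
        # two nodes, drag gamma each: length relaxes as exp(-2kt/gamma)
        k, gamma = 0.4, 2.0
        mesh = SimpleNamespace(
            edges=np.array([[0, 1]]), rest_lengths=np.array([1.0]),
            compartment=np.array([0]),
        )
        pos = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]])
        params = em.ElasticParams.uniform(k)
        dt = 1e-4
        n = 2000
        p = pos.copy()
        for _ in range(n):
            p = step_overdamped(p, mesh, params, gamma, dt)
        L = np.linalg.norm(p[1] - p[0])
        expected = 1.0 + 0.2 * np.exp(-2.0 * k * n * dt / gamma)
        assert L == pytest.approx(expected, abs=1e-4)

    def test_ib_equilibrium_unchanged(self, ball_domain):
        mesh = SimpleNamespace(
            edges=np.array([[0, 1]]), rest_lengths=np.array([10.0]),
            compartment=np.array([0]),
        )
        pos = np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        new = step_ib(pos, mesh, em.ElasticParams.uniform(0.1), ball_domain, 1.0)
        np.testing.assert_allclose(new, pos, atol=1e-12)

    def test_ib_stretched_spring_monotone_decay(self, ball_domain, spring_system):
        mesh, pos = spring_system
        back = ImmersedBoundaryBackend(ball_domain)
        params = em.ElasticParams.uniform(0.01)
        p = pos.copy()
        lengths = []
        for _ in range(25):
            p = step_ib(p, mesh, params, ball_domain, 2.0, backend=back)
            lengths.append(np.linalg.norm(p[1] - p[0]))
        diffs = np.diff(lengths)
        assert np.all(diffs < 1e-12)
        assert lengths[-1] > mesh.rest_lengths[0]

    def test_ib_step_halving_first_order(self, ball_domain, spring_system):
        mesh, pos = spring_system
        back = ImmersedBoundaryBackend(ball_domain)
        params = em.ElasticParams.uniform(0.01)

        def run(dt, T=16.0):
            p = pos.copy()
            for _ in range(int(round(T / dt))):
                p = step_ib(p, mesh, params, ball_domain, dt, backend=back)
            return p

        ref = run(1.0)
        e1 = np.abs(run(4.0) - ref).max()
        e2 = np.abs(run(2.0) - ref).max()
        assert 1.4 < e1 / e2 < 3.5  # explicit Euler: error ~ dt

    def test_backend_consistency_fitted_drag(self, ball_domain, spring_system):
        # overdamped with the pairwise-probe drag reproduces the IB
        # relaxation time within the stated 20% calibration band
        mesh, pos = spring_system
        back = ImmersedBoundaryBackend(ball_domain)
        k = 0.01
        params = em.ElasticParams.uniform(k)
        probe = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        v = back.velocities(pos, probe)
        gamma_rel = 2.0 / (v[1, 0] - v[0, 0])
        dt = 0.05 * gamma_rel / k
        p = pos.copy()
        ts, Ls = [], []
        for i in range(60):
            p = step_ib(p, mesh, params, ball_domain, dt, backend=back)
            ts.append((i + 1) * dt)
            Ls.append(np.linalg.norm(p[1] - p[0]))
        tau_ib = -1.0 / np.polyfit(ts, np.log(np.array(Ls) - 24.0), 1)[0]
        tau_od = gamma_rel / (2.0 * k)
        assert tau_ib == pytest.approx(tau_od, rel=0.2)

    def test_energy_dissipation_both_backends(self, ball_domain, spring_system, rng):
        mesh, pos = spring_system
        params = em.ElasticParams.uniform(0.01)

        def energies(stepper, n, dt):
            p = pos.copy()
            out = []
            for _ in range(n):
                p = stepper(p, dt)
                out.append(em.elastic_energy(p, mesh.edges, mesh.rest_lengths, 0.01))
            return out

        back = ImmersedBoundaryBackend(ball_domain)
        e_ib = energies(lambda p, dt: step_ib(p, mesh, params, ball_domain, dt, backend=back), 15, 2.0)
        e_od = energies(lambda p, dt: step_overdamped(p, mesh, params, 1.0, dt), 15, 2.0)
        assert np.all(np.diff(e_ib) <= 1e-14)
        assert np.all(np.diff(e_od) <= 1e-14)

    def test_instability_detected(self):
        mesh = SimpleNamespace(
            edges=np.array([[0, 1]]), rest_lengths=np.array([1.0]),
            compartment=np.array([0]),
        )
        pos = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        with pytest.raises(em.InstabilityError):
            step_overdamped(pos, mesh, em.ElasticParams.uniform(10.0), 0.01, 10.0)
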