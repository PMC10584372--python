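"""Fluid-structure coupling backends.

Two dynamics backends drive the spring networks:

* an immersed-boundary backend: elastic node forces are spread to the fluid
  nodes with a compact distance-weighted kernel, the resulting Stokes flow in
  the vitelline shell is solved with regularized Stokeslets (no-slip shell
  enforced by collocation tractions), and fluid velocities are interpolated
  back to the solid nodes;
* an overdamped backend in which the fluid is replaced by a constant drag
  coefficient per node (velocity = force / gamma).

Stokes flow is inertia-free and linear: velocities are linear in the applied
forces, which the constraint-force solver in `pull_protocol` relies on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial import cKDTree

from .elastic_network import spring_forces
from .geometry import FluidDomain
from .records import InstabilityError


@dataclass(frozen=True)
class CouplingKernel:
    """Compactly supported distance-weighting kernel for solid/fluid transfer.

    Raw weights (1 - (d/r)^2)^3 are normalized per solid node so that the
    weights over the support form a partition of unity: interpolation
    reproduces constant fields exactly, and spreading conserves total force.
    """

    support_radius: float

    def raw_weight(self, dist: np.ndarray) -> np.ndarray:
        s = np.clip(dist / self.support_radius, 0.0, 1.0)
        return (1.0 - s**2) ** 3

    def weight_matrix(self, solid_nodes: np.ndarray, fluid_nodes: np.ndarray) -> sp.csr_matrix:
        """(n_solid, n_fluid) row-stochastic sparse weight matrix."""
        tree = cKDTree(fluid_nodes)
        neighbours = tree.query_ball_point(solid_nodes, self.support_radius)
        rows, cols, vals = [], [], []
        for i, nbr in enumerate(neighbours):
            if len(nbr) == 0:
                raise ValueError(
                    f"solid node {i} has no fluid node within the kernel support"
                )
            nbr = np.asarray(nbr)
            w = self.raw_weight(np.linalg.norm(fluid_nodes[nbr] - solid_nodes[i], axis=1))
            total = w.sum()
            if total <= 0:
                raise ValueError(f"solid node {i} has zero kernel weight sum")
            rows.append(np.full(len(nbr), i))
            cols.append(nbr)
            vals.append(w / total)
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(solid_nodes), len(fluid_nodes)),
        ).tocsr()


def spread_forces(
    solid_nodes: np.ndarray,
    solid_forces: np.ndarray,
    domain: FluidDomain,
    kernel: CouplingKernel,
) -> np.ndarray:
    """Transfer solid node forces to a fluid force density (nN/um^3).

    Exactly conservative: sum(density * nodal volume) equals the total solid
    force.
    """
    W = kernel.weight_matrix(solid_nodes, domain.nodes)
    nodal_force = W.T @ solid_forces
    return nodal_force / domain.node_volumes[:, None]


def interpolate_velocities(
    fluid_velocities: np.ndarray,
    solid_nodes: np.ndarray,
    domain: FluidDomain,
    kernel: CouplingKernel,
) -> np.ndarray:
    """Transfer fluid node velocities back to the solid nodes.

    Uses the same weights as `spread_forces`, so interpolation is the adjoint
    of spreading under the volume-weighted inner product on the fluid and the
    plain dot product on the solid.
    """
    W = kernel.weight_matrix(solid_nodes, domain.nodes)
    return W @ fluid_velocities


def _reg_stokeslet_blocks(
    targets: np.ndarray, sources: np.ndarray, eps: float, mu: float
) -> np.ndarray:
    """Dense (3T, 3S) regularized-Stokeslet matrix (Cortez blob)."""
    d = targets[:, None, :] - sources[None, :, :]
    r2 = np.einsum("tsk,tsk->ts", d, d)
    denom = (r2 + eps**2) ** 1.5
    A = (r2 + 2.0 * eps**2) / denom
    blocks = (
        A[:, :, None, None] * np.eye(3)[None, None]
        + d[:, :, :, None] * d[:, :, None, :] / denom[:, :, None, None]
    )
    T, S = len(targets), len(sources)
    return blocks.transpose(0, 2, 1, 3).reshape(3 * T, 3 * S) / (8.0 * np.pi * mu)


class StokesSolver:
    """Regularized-Stokeslet solve of the shell-bounded Stokes problem.

    Nodal forces act as regularized point forces; unknown tractions at the
    shell collocation nodes enforce the no-slip vitelline boundary.  The
    mobility uses the volume-dominant (interior) viscosity; the thin
    low-viscosity perivitelline film acts as a lubrication layer and is not
    resolved in the mobility.
    """

    def __init__(self, domain: FluidDomain, eps: float | None = None, mu: float | None = None):
        self.domain = domain
        self.eps = float(eps) if eps is not None else 0.75 * domain.resolution
        if mu is None:
            mu = float(
                np.average(domain.viscosity, weights=np.maximum(domain.node_volumes, 1e-30))
            )
        self.mu = float(mu)
        self._S = _reg_stokeslet_blocks(domain.nodes, domain.nodes, self.eps, self.mu)
        sh = np.where(domain.shell_mask)[0]
        self._shell_idx = sh
        shell_dofs = (sh[:, None] * 3 + np.arange(3)[None, :]).ravel()
        self._shell_dofs = shell_dofs
        S_ss = self._S[np.ix_(shell_dofs, shell_dofs)]
        try:
            self._lu = lu_factor(S_ss)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"shell mobility factorization failed: {exc}") from exc
        if not np.all(np.isfinite(self._lu[0])):
            raise RuntimeError("shell mobility system is singular or ill-conditioned")

    def shell_reactions(self, forces: np.ndarray) -> np.ndarray:
        """Shell tractions (as point forces) enforcing zero shell velocity."""
        f = forces.ravel()
        u_shell = self._S[self._shell_dofs] @ f
        g = lu_solve(self._lu, -u_shell)
        if not np.all(np.isfinite(g)):
            raise RuntimeError("shell constraint solve produced non-finite tractions")
        return g

    def solve(self, forces: np.ndarray) -> np.ndarray:
        """Velocities at all fluid nodes given nodal forces (nN)."""
        f = forces.ravel().copy()
        g = self.shell_reactions(forces)
        f[self._shell_dofs] += g
        u = self._S @ f
        out = u.reshape(-1, 3)
        out[self.domain.shell_mask] = 0.0  # exact at collocation nodes
        return out

    def velocity_at(self, points: np.ndarray, forces: np.ndarray) -> np.ndarray:
        """Evaluate the solved flow field at arbitrary points."""
        f = forces.ravel().copy()
        g = self.shell_reactions(forces)
        f[self._shell_dofs] += g
        S_eval = _reg_stokeslet_blocks(np.atleast_2d(points), self.domain.nodes, self.eps, self.mu)
        return (S_eval @ f).reshape(-1, 3)


def get_stokes_solver(domain: FluidDomain, eps: float | None = None) -> StokesSolver:
    """Cached StokesSolver for a domain (geometry is fixed, so reuse is safe)."""
    key = ("_stokes_solver", eps)
    cache = getattr(domain, "_solver_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(domain, "_solver_cache", cache)
    if key not in cache:
        cache[key] = StokesSolver(domain, eps=eps)
    return cache[key]


def solve_stokes(
    domain: FluidDomain, force_density: np.ndarray, eps: float | None = None
) -> np.ndarray:
    """Discrete Stokes solve: fluid force density (nN/um^3) -> velocities (um/s)."""
    force_density = np.asarray(force_density, dtype=float)
    if not np.all(np.isfinite(force_density)):
        raise ValueError("force density must be finite")
    solver = get_stokes_solver(domain, eps=eps)
    forces = force_density * domain.node_volumes[:, None]
    return solver.solve(forces)


class OverdampedBackend:
    """Constant-drag dynamics: node velocity = net force / gamma."""

    is_diagonal = True

    def __init__(self, gamma: float):
        if gamma <= 0:
            raise ValueError("gamma must be > 0")
        self.gamma = float(gamma)

    def velocities(self, positions: np.ndarray, forces: np.ndarray) -> np.ndarray:
        return forces / self.gamma

    def effective_gamma(self, positions=None, probe_node: int | None = None) -> float:
        return self.gamma


class ImmersedBoundaryBackend:
    """Five-sub-step immersed-boundary coupling to the shell-bounded Stokes flow.

    The solid/fluid weight matrix is rebuilt lazily, only once the solid
    nodes have moved a meaningful fraction of the kernel support since the
    last build (the transfer weights vary smoothly with position).
    """

    is_diagonal = False

    def __init__(
        self,
        domain: FluidDomain,
        kernel: CouplingKernel | None = None,
        eps: float | None = None,
        weight_rebuild_fraction: float = 0.1,
    ):
        self.domain = domain
        self.kernel = kernel or CouplingKernel(support_radius=2.0 * domain.resolution)
        self.solver = get_stokes_solver(domain, eps=eps)
        self._w_positions: np.ndarray | None = None
        self._W = None
        self._rebuild_dist = weight_rebuild_fraction * self.kernel.support_radius

    def _weights(self, positions: np.ndarray):
        if (
            self._W is None
            or self._w_positions.shape != positions.shape
            or np.max(np.abs(positions - self._w_positions)) > self._rebuild_dist
        ):
            self._W = self.kernel.weight_matrix(positions, self.domain.nodes)
            self._w_positions = positions.copy()
        return self._W

    def velocities(self, positions: np.ndarray, forces: np.ndarray) -> np.ndarray:
        W = self._weights(positions)
        nodal_force = W.T @ forces  # conservative spread (volumes cancel below)
        u_fluid = self.solver.solve(nodal_force)
        return W @ u_fluid

    def effective_gamma(self, positions: np.ndarray, probe_node: int = 0) -> float:
        """Drag scale from a unit-force probe (used for time-step selection)."""
        f = np.zeros_like(positions)
        f[probe_node, 0] = 1.0
        v = self.velocities(positions, f)
        speed = np.linalg.norm(v[probe_node])
        if speed <= 0:
            raise RuntimeError("probe produced zero velocity; cannot estimate drag")
        return 1.0 / speed


def _advect(positions, velocities, dt, min_rest_length):
    step = velocities * dt
    if np.max(np.linalg.norm(step, axis=1)) > 0.5 * min_rest_length:
        raise InstabilityError(
            "time step moved a node farther than half a rest length; reduce dt"
        )
    return positions + step


def step_ib(
    positions: np.ndarray,
    mesh,
    params,
    domain: FluidDomain,
    dt: float,
    external_forces: np.ndarray | None = None,
    kernel: CouplingKernel | None = None,
    backend: ImmersedBoundaryBackend | None = None,
) -> np.ndarray:
    """One immersed-boundary step: the five ordered sub-steps.

    (1) elastic + external forces at solid nodes, (2) spread to the fluid,
    (3) Stokes solve, (4) interpolate velocities back, (5) advect the solid
    nodes by dt.
    """
    from .elastic_network import spring_k_array

    if backend is None:
        backend = ImmersedBoundaryBackend(domain, kernel=kernel)
    f = spring_forces(positions, mesh.edges, mesh.rest_lengths, spring_k_array(mesh, params))
    if external_forces is not None:
        f = f + external_forces
    v = backend.velocities(positions, f)
    return _advect(positions, v, dt, float(np.min(mesh.rest_lengths)))


def step_overdamped(
    positions: np.ndarray,
    mesh,
    params,
    gamma: float,
    dt: float,
    external_forces: np.ndarray | None = None,
) -> np.ndarray:
    """One constant-drag step: velocity = (elastic + external force)/gamma."""
    from .elastic_network import spring_k_array

    f = spring_forces(positions, mesh.edges, mesh.rest_lengths, spring_k_array(mesh, params))
    if external_forces is not None:
        f = f + external_forces
    v = OverdampedBackend(gamma).velocities(positions, f)
    return _advect(positions, v, dt, float(np.min(mesh.rest_lengths)))
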