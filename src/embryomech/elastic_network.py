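"""Hookean spring-network elasticity: forces, energy, stress, sheet moduli.

Springs are linear central forces with fixed rest lengths (no remodeling, no
bending stiffness).  The per-spring stress is the signed spring tension
k*(L - L0), tension positive.  A triangulated patch of such springs behaves
as an isotropic elastic sheet; `measure_sheet_moduli` extracts its 2D
Young's modulus and Poisson ratio numerically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import APICAL, BASAL, COMPARTMENT_NAMES, LATERAL, EmbryoMesh

_L_TOL = 1e-12


@dataclass(frozen=True)
class ElasticParams:
    """Compartment-specific spring constants (nN/um).

    The uniform-elasticity model is the special case where all three are
    equal.  The compartment split matters because the apical triangulated
    surface is topologically stiff while the lateral/basal structures form a
    floppy (under-constrained) network.
    """

    k_apical: float
    k_lateral: float
    k_basal: float

    def __post_init__(self) -> None:
        if min(self.k_apical, self.k_lateral, self.k_basal) < 0:
            raise ValueError("spring constants must be >= 0")

    @classmethod
    def uniform(cls, k: float) -> "ElasticParams":
        return cls(k, k, k)

    @property
    def k_max(self) -> float:
        return max(self.k_apical, self.k_lateral, self.k_basal)

    def per_spring(self, compartment: np.ndarray) -> np.ndarray:
        table = np.array([self.k_apical, self.k_lateral, self.k_basal])
        return table[np.asarray(compartment, dtype=int)]


def spring_k_array(mesh: EmbryoMesh, params: ElasticParams) -> np.ndarray:
    return params.per_spring(mesh.compartment)


def _lengths_and_units(positions: np.ndarray, edges: np.ndarray):
    d = positions[edges[:, 1]] - positions[edges[:, 0]]
    L = np.linalg.norm(d, axis=1)
    if np.any(L < _L_TOL):
        raise ValueError("coincident spring endpoints: spring direction undefined")
    return d, L


def spring_forces(
    positions: np.ndarray,
    edges: np.ndarray,
    rest_lengths: np.ndarray,
    k: np.ndarray | float,
) -> np.ndarray:
    """Per-node elastic forces; exact negative gradient of the elastic energy.

    A stretched spring pulls its endpoints together: the force on node i from
    spring (i, j) is k*(L - L0) * unit(i -> j).
    """
    d, L = _lengths_and_units(positions, edges)
    t = np.asarray(k) * (L - rest_lengths)  # tension, nN
    f_pair = (t / L)[:, None] * d  # force on edge[:,0] toward edge[:,1]
    forces = np.zeros_like(positions)
    np.add.at(forces, edges[:, 0], f_pair)
    np.add.at(forces, edges[:, 1], -f_pair)
    return forces


def elastic_energy(
    positions: np.ndarray,
    edges: np.ndarray,
    rest_lengths: np.ndarray,
    k: np.ndarray | float,
) -> float:
    _, L = _lengths_and_units(positions, edges)
    return float(0.5 * np.sum(np.asarray(k) * (L - rest_lengths) ** 2))


@dataclass
class StressField:
    """Per-spring signed tension k*(L - L0) (nN); tension positive."""

    per_spring: np.ndarray

    def mean_abs(self, mask: np.ndarray | None = None) -> float:
        s = self.per_spring if mask is None else self.per_spring[mask]
        return float(np.mean(np.abs(s))) if len(s) else 0.0


def stress_field(
    positions: np.ndarray,
    edges: np.ndarray,
    rest_lengths: np.ndarray,
    k: np.ndarray | float,
) -> StressField:
    _, L = _lengths_and_units(positions, edges)
    return StressField(per_spring=np.asarray(k) * (L - rest_lengths))


def mesh_stress_field(mesh: EmbryoMesh, positions: np.ndarray, params: ElasticParams) -> StressField:
    return stress_field(positions, mesh.edges, mesh.rest_lengths, spring_k_array(mesh, params))


def stiffness_matrix(
    positions: np.ndarray,
    edges: np.ndarray,
    rest_lengths: np.ndarray,
    k: np.ndarray | float,
) -> sp.csr_matrix:
    """Analytic Hessian of the elastic energy at the given configuration.

    Per spring the block is k*[d^ d^T + (1 - L0/L)(I - d^ d^T)]; at the
    stress-free reference this reduces to the central-force k*d^ d^T, whose
    null space encodes the floppy modes of the network.
    """
    d, L = _lengths_and_units(positions, edges)
    dim = positions.shape[1]
    dhat = d / L[:, None]
    k = np.broadcast_to(np.asarray(k, dtype=float), (len(edges),))
    outer = dhat[:, :, None] * dhat[:, None, :]
    eye = np.eye(dim)[None, :, :]
    blocks = k[:, None, None] * (outer + (1.0 - rest_lengths / L)[:, None, None] * (eye - outer))

    n = len(positions)
    rows, cols, vals = [], [], []
    for (sa, sb, sign) in (
        (edges[:, 0], edges[:, 0], 1.0),
        (edges[:, 1], edges[:, 1], 1.0),
        (edges[:, 0], edges[:, 1], -1.0),
        (edges[:, 1], edges[:, 0], -1.0),
    ):
        for a in range(dim):
            for b in range(dim):
                rows.append(sa * dim + a)
                cols.append(sb * dim + b)
                vals.append(sign * blocks[:, a, b])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n * dim, n * dim)).tocsr()


def count_zero_modes(K: sp.spmatrix, tol: float = 1e-8) -> int:
    """Dimension of the stiffness-matrix null space by dense eigendecomposition.

    Intended for small patches (brute force); the threshold is relative to
    the largest eigenvalue.
    """
    w = np.linalg.eigvalsh(K.toarray())
    scale = max(abs(w[-1]), 1.0)
    return int(np.sum(np.abs(w) < tol * scale))


@dataclass
class SheetModuli:
    """Effective 2D sheet moduli of a triangulated spring network.

    ``youngs_E`` has units of nN/um (a 2D sheet modulus, same units as k for
    this discretization); ``poisson_nu`` is dimensionless.
    """

    youngs_E: float
    poisson_nu: float


def measure_sheet_moduli(
    patch,
    k: float | None = None,
    strain: float = 0.01,
    boundary_rows: int = 2,
) -> SheetModuli:
    """Uniaxial stretch test on a flat triangulated patch.

    The two x-extremal node columns are clamped in x (left fixed, right
    displaced by strain * span) with transverse motion left free, the interior
    relaxes to equilibrium (exact linear solve about the stress-free state),
    and the sheet modulus is (edge reaction)/(width * strain).  The Poisson
    ratio is the transverse/axial strain ratio of an affine fit in the bulk,
    excluding ``boundary_rows`` rows near every border to avoid clamped-edge
    artifacts.
    """
    pos = np.asarray(patch.positions, dtype=float)
    if pos.shape[1] != 2:
        raise ValueError("sheet moduli are measured on flat 2D patches")
    edges = np.asarray(patch.edges)
    L0 = np.asarray(patch.rest_lengths)
    kval = float(patch.k if k is None else k)
    spacing = float(patch.spacing)

    x, y = pos[:, 0], pos[:, 1]
    xmin, xmax = x.min(), x.max()
    # clamp the extremal zigzag columns (row offset spreads them over s/2)
    left = np.where(x < xmin + 0.6 * spacing)[0]
    right = np.where(x > xmax - 0.6 * spacing)[0]
    span = xmax - xmin

    K = stiffness_matrix(pos, edges, L0, kval)
    n = len(pos)
    u = np.zeros(2 * n)
    constrained = np.zeros(2 * n, dtype=bool)
    constrained[left * 2] = True
    constrained[right * 2] = True
    u[right * 2] = strain * span
    # pin transverse translation via the node nearest the patch centroid
    centre = int(np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1)))
    constrained[centre * 2 + 1] = True

    free = ~constrained
    Kff = K[free][:, free]
    rhs = -K[free][:, constrained] @ u[constrained]
    u_free = spla.spsolve(Kff.tocsc(), rhs)
    if not np.all(np.isfinite(u_free)):
        raise RuntimeError("sheet-moduli relaxation failed: singular stiffness")
    u[free] = u_free
    residual = np.linalg.norm(Kff @ u_free - rhs) / max(np.linalg.norm(rhs), 1e-30)
    if residual > 1e-6:
        raise RuntimeError(f"sheet-moduli relaxation not converged: residual {residual:.2e}")

    # reaction force on the moving clamp; the effective width counts one
    # strip per bond row (node extent + one row spacing), otherwise the
    # modulus carries an O(1/rows) bias
    reaction = (K @ u)[right * 2].sum()
    ys = np.unique(np.round(y / (0.1 * spacing)).astype(int)) * 0.1 * spacing
    row_dy = float(np.min(np.diff(ys))) if len(ys) > 1 else spacing
    width = (y.max() - y.min()) + row_dy

    # bulk affine fit over the central third (in x) with the clamp boundary
    # layer excluded: the modulus uses the bulk axial strain rather than the
    # end-to-end strain (the clamped columns carry a Saint-Venant layer)
    bl = boundary_rows * spacing
    cx = 0.5 * (xmin + xmax)
    half = (xmax - xmin) / 6.0
    bulk = (
        (np.abs(x - cx) < half)
        & (y > y.min() + bl)
        & (y < y.max() - bl)
    )
    disp = u.reshape(n, 2)[bulk]
    p = pos[bulk] - pos[bulk].mean(axis=0)
    A = np.column_stack([p, np.ones(len(p))])
    Gx, *_ = np.linalg.lstsq(A, disp[:, 0], rcond=None)
    Gy, *_ = np.linalg.lstsq(A, disp[:, 1], rcond=None)
    exx, eyy = Gx[0], Gy[1]
    nu = -eyy / exx
    E = reaction / (width * exx)
    return SheetModuli(youngs_E=float(E), poisson_nu=float(nu))
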