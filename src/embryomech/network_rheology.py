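"""Flat spring-lattice rheology: stiff (triangular) vs floppy (hexagonal) nets.

A triangular lattice has more central-force constraints than degrees of
freedom (Maxwell-rigid); a honeycomb lattice is under-constrained ("floppy"),
admitting zero-energy deformations.  Both are pulled at an interior node at
constant velocity against a uniform drag, then released, mirroring the
simplified model in which the viscous cytoplasm is replaced by a constant
drag force.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic_network import spring_forces
from .records import HOLDING, LOADING, UNLOADING, InstabilityError, SimulationRecord

TRIANGULAR, HEXAGONAL = "triangular", "hexagonal"


@dataclass
class NetworkPatch:
    """Flat 2D spring lattice with a pinned rim and a central load node."""

    topology: str
    positions: np.ndarray  # (N, 2)
    edges: np.ndarray  # (S, 2)
    rest_lengths: np.ndarray
    k: float
    gamma: float
    pinned: np.ndarray  # (N,) bool
    load_node: int
    spacing: float

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_free(self) -> int:
        return int((~self.pinned).sum())

    def maxwell_excess(self) -> int:
        """(#constraints) - (#internal degrees of freedom) of the unpinned
        network: >= 0 suggests rigid, < 0 guarantees floppy modes."""
        return int(len(self.edges) - (2 * self.n_nodes - 3))


def _triangular_sites(n_rows: int, n_cols: int, spacing: float):
    """Triangular-lattice sites with skew (i, j) indices arranged in a
    near-rectangular patch (row offset absorbed into the j range)."""
    idx, pts = [], []
    for i in range(n_rows):
        for j0 in range(n_cols):
            j = j0 - i // 2
            x = (j + 0.5 * i) * spacing
            y = i * spacing * np.sqrt(3) / 2
            idx.append((i, j))
            pts.append((x, y))
    return idx, np.asarray(pts)


_NEIGHBOUR_STEPS = ((0, 1), (1, 0), (1, -1))


def _lattice_edges(index_of: dict):
    edges = []
    for (i, j), a in index_of.items():
        for di, dj in _NEIGHBOUR_STEPS:
            b = index_of.get((i + di, j + dj))
            if b is not None:
                edges.append((a, b))
    return np.asarray(edges, dtype=int)


def _finish_patch(topology, pts, edges, spacing, k, gamma, pin_margin):
    rest = np.linalg.norm(pts[edges[:, 1]] - pts[edges[:, 0]], axis=1)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pinned = (
        (pts[:, 0] < lo[0] + pin_margin)
        | (pts[:, 0] > hi[0] - pin_margin)
        | (pts[:, 1] < lo[1] + pin_margin)
        | (pts[:, 1] > hi[1] - pin_margin)
    )
    centre = (lo + hi) / 2
    dist = np.linalg.norm(pts - centre, axis=1)
    dist[pinned] = np.inf
    # lowest-index tie-break among nodes nearest the centre
    dmin = dist.min()
    load_node = int(np.flatnonzero(dist <= dmin + 1e-9 * spacing)[0])
    return NetworkPatch(
        topology=topology,
        positions=pts,
        edges=edges,
        rest_lengths=rest,
        k=float(k),
        gamma=float(gamma),
        pinned=pinned,
        load_node=load_node,
        spacing=float(spacing),
    )


def triangular_patch(
    n_rows: int = 30,
    n_cols: int = 30,
    spacing: float = 8.0,
    k: float = 0.035,
    gamma: float = 1.0,
) -> NetworkPatch:
    """Maxwell-rigid triangular lattice patch (6-coordinated in the bulk)."""
    idx, pts = _triangular_sites(n_rows, n_cols, spacing)
    index_of = {ij: a for a, ij in enumerate(idx)}
    edges = _lattice_edges(index_of)
    return _finish_patch(TRIANGULAR, pts, edges, spacing, k, gamma, 0.6 * spacing)


def hexagonal_patch(
    n_rows: int = 30,
    n_cols: int = 30,
    spacing: float = 8.0,
    k: float = 0.035,
    gamma: float = 1.0,
) -> NetworkPatch:
    """Floppy honeycomb patch: a triangular lattice with one 3-coloring
    sublattice removed, leaving 3-coordinated vertices."""
    idx, pts = _triangular_sites(n_rows, n_cols, spacing)
    keep = [(ij, p) for ij, p in zip(idx, pts) if (ij[0] + 2 * ij[1]) % 3 != 0]
    index_of = {ij: a for a, (ij, _) in enumerate(keep)}
    pts = np.asarray([p for _, p in keep])
    edges = _lattice_edges(index_of)
    return _finish_patch(HEXAGONAL, pts, edges, spacing, k, gamma, 1.1 * spacing)


def make_patch(topology: str, **kw) -> NetworkPatch:
    if topology == TRIANGULAR:
        return triangular_patch(**kw)
    if topology == HEXAGONAL:
        return hexagonal_patch(**kw)
    raise ValueError(f"unknown topology {topology!r}")


def run_patch_experiment(
    patch: NetworkPatch,
    protocol,
    record_interval: float = 1.0,
    dt: float | None = None,
) -> SimulationRecord:
    """Load/hold/release the patch at its load node under constant drag.

    The load node is driven at the protocol's speed along its pull direction;
    the instantaneous external force required is gamma*v - F_elastic at that
    node (exact for diagonal drag).  The rim stays pinned throughout.
    """
    if patch.pinned[patch.load_node]:
        raise ValueError("load node must be an interior (unpinned) node")
    direction = np.asarray(protocol.pull_direction, dtype=float)[:2]
    direction = direction / np.linalg.norm(direction)

    pos = patch.positions.copy()
    x0 = pos[patch.load_node].copy()
    free = ~patch.pinned
    ln = patch.load_node
    if dt is None:
        dt = min(0.1 * patch.gamma / patch.k, record_interval, 1.0)
    min_L0 = float(patch.rest_lengths.min())

    times, disps, forces, phases = [], [], [], []
    rms = []
    t = 0.0

    def record(phase, applied):
        times.append(t)
        disps.append(float((pos[ln] - x0) @ direction))
        forces.append(applied)
        phases.append(phase)
        rms.append(float(np.sqrt(np.mean(np.sum((pos[free] - patch.positions[free]) ** 2, axis=1)))))

    def run_phase(phase, duration, v_imp, max_halvings=8):
        nonlocal pos, t
        if duration <= 0:
            return
        n_steps = max(1, int(round(duration / dt)))
        dt_eff = duration / n_steps
        next_rec = t + record_interval
        halvings = 0
        step_i = 0
        while step_i < n_steps:
            f = spring_forces(pos, patch.edges, patch.rest_lengths, patch.k)
            if v_imp is not None:
                f_ext = patch.gamma * v_imp - f[ln]
                f[ln] += f_ext
                applied = float(f_ext @ direction)
            else:
                applied = 0.0
            v = f / patch.gamma
            v[patch.pinned] = 0.0
            step = v * dt_eff
            if np.max(np.linalg.norm(step, axis=1)) > 0.5 * min_L0:
                # stiff transient (e.g. just after release): halve the step
                if halvings >= max_halvings:
                    raise InstabilityError(
                        f"patch instability during {phase} at t={t:.2f}s"
                    )
                halvings += 1
                n_steps = (n_steps - step_i) * 2 + step_i
                dt_eff /= 2.0
                continue
            pos = pos + step
            t += dt_eff
            step_i += 1
            if t >= next_rec - 1e-9:
                record(phase, applied)
                next_rec += record_interval

    record(LOADING, 0.0)
    run_phase(LOADING, protocol.loading_duration, protocol.loading_speed * direction)
    run_phase(HOLDING, protocol.holding_duration, np.zeros(2))
    run_phase(UNLOADING, protocol.unloading_duration, None)

    return SimulationRecord(
        times=np.asarray(times),
        displacement=np.asarray(disps),
        force=np.asarray(forces),
        phase=np.asarray(phases, dtype=object),
        extras={"rms_displacement": np.asarray(rms)},
        meta={"dt": dt, "topology": patch.topology, "k": patch.k, "gamma": patch.gamma},
    )


def effective_relaxation_time(record: SimulationRecord, floor: float = 1e-6) -> float:
    """Relaxation time of the approach to the undeformed reference state.

    Log-linear slope of (RMS deformation)/(RMS at release) over the whole
    unloading window, with no asymptote granted: a floppy network that stalls
    in a deformed zero-energy configuration therefore reports a long time,
    which is the observable that distinguishes floppy from stiff relaxation.
    """
    m = record.phase_mask(UNLOADING)
    if not m.any():
        raise ValueError("record has no unloading phase")
    t = record.times[m]
    t = t - t[0]
    d = record.extras.get("rms_displacement", record.displacement)[m]
    if d[0] <= 0:
        return 0.0
    y = d / d[0]
    keep = y > floor
    slope = np.polyfit(t[keep], np.log(y[keep]), 1)[0]
    if slope >= 0:
        return np.inf
    return float(-1.0 / slope)


def residual_deformation(record: SimulationRecord, time: float) -> float:
    """Fraction of the network deformation remaining ``time`` seconds after release.

    Measured as the RMS node displacement normalized by its value at the
    start of unloading (1.0 at time 0 by definition; 0.0 once fully relaxed).
    """
    m = record.phase_mask(UNLOADING)
    if not m.any():
        raise ValueError("record has no unloading phase")
    t_u = record.times[m]
    target = t_u[0] + time
    if time < 0 or target > t_u[-1] + 1e-9:
        raise ValueError(f"time {time} s outside the recorded unloading window")
    series = record.extras.get("rms_displacement", record.displacement)[m]
    ref = series[0]
    if ref <= 0:
        return 0.0
    idx = int(np.argmin(np.abs(t_u - target)))
    return float(series[idx] / ref)
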