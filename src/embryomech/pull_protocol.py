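"""In-silico cantilever pulling: load / hold / unload on a spring-network mesh.

The cantilever contact is modelled as a rigid imposed displacement of the two
nodes of one lateral cell edge.  The applied force is extracted with a
Lagrange-multiplier solve: at every constrained step we find the external
force on the constrained nodes that, combined with the elastic forces and the
backend's (linear) force-to-velocity map, makes them move at exactly the
imposed velocity.

A free-floating mesh under the overdamped backend accumulates rigid-body
drift from the net applied impulse (the shell-bounded fluid of the full model
prevents this).  Records therefore also carry a drift-corrected series,
``displacement_corotated``, measured in the best-fit rigid-body frame.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .elastic_network import ElasticParams, spring_forces, spring_k_array
from .records import HOLDING, LOADING, UNLOADING, InstabilityError, SimulationRecord


@dataclass(frozen=True)
class PullProtocol:
    """Cantilever driving protocol.

    Defaults follow the experimental protocol: the cantilever base translates
    at 0.5 um/s for ~60 s (loading), is held in place for ~60 s (holding),
    and is then withdrawn so the tissue relaxes freely (unloading).
    """

    loading_speed: float = 0.5
    loading_duration: float = 60.0
    holding_duration: float = 60.0
    unloading_duration: float = 120.0
    pulled_edge: tuple | None = None
    pull_direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.loading_speed <= 0:
            raise ValueError("loading_speed must be > 0")
        if self.loading_duration <= 0:
            raise ValueError("loading_duration must be > 0")
        if self.holding_duration < 0 or self.unloading_duration < 0:
            raise ValueError("durations must be >= 0")

    def direction(self, dim: int = 3) -> np.ndarray:
        d = np.asarray(self.pull_direction, dtype=float)[:dim]
        n = np.linalg.norm(d)
        if n <= 0:
            raise ValueError("pull_direction must be a nonzero vector")
        return d / n

    def with_(self, **kw) -> "PullProtocol":
        return replace(self, **kw)


def kabsch_displacement(reference: np.ndarray, current: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Displacement of ``points`` after removing the best-fit rigid motion.

    Finds the rigid transform (R, t) minimizing ||R @ current + t - reference||
    over all nodes and returns (R @ points + t) - corresponding reference
    points.  ``points`` must be rows of ``current``.
    """
    c_ref = reference.mean(axis=0)
    c_cur = current.mean(axis=0)
    H = (current - c_cur).T @ (reference - c_ref)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0] * (H.shape[0] - 1) + [d])
    R = Vt.T @ D @ U.T
    return (points - c_cur) @ R.T + c_ref


def constrained_mobility(positions: np.ndarray, backend, constrained_nodes) -> np.ndarray:
    """Backend mobility restricted to the constrained dofs (unit-force probes)."""
    constrained_nodes = np.atleast_1d(np.asarray(constrained_nodes, dtype=int))
    dim = positions.shape[1]
    c = len(constrained_nodes)
    M = np.empty((c * dim, c * dim))
    probe = np.zeros_like(positions)
    for a, node in enumerate(constrained_nodes):
        for ax in range(dim):
            probe[node, ax] = 1.0
            M[:, a * dim + ax] = backend.velocities(positions, probe)[constrained_nodes].ravel()
            probe[node, ax] = 0.0
    return M


def constraint_force(
    positions: np.ndarray,
    mesh,
    params: ElasticParams,
    backend,
    constrained_nodes: np.ndarray,
    v_imposed: np.ndarray,
    direction: np.ndarray | None = None,
    mobility: np.ndarray | None = None,
):
    """External force making the constrained nodes move at the imposed velocity.

    Solves M_cc f_ext = v_imposed - v_elastic, where M_cc is the backend's
    mobility restricted to the constrained degrees of freedom (assembled by
    unit-force probes; diagonal 1/gamma for the overdamped backend).  Returns
    (per-node force array (c, dim), scalar force along ``direction``).
    """
    constrained_nodes = np.atleast_1d(np.asarray(constrained_nodes, dtype=int))
    dim = positions.shape[1]
    v_imposed = np.broadcast_to(
        np.asarray(v_imposed, dtype=float), (len(constrained_nodes), dim)
    )

    f_el = spring_forces(positions, mesh.edges, mesh.rest_lengths, spring_k_array(mesh, params))
    v0 = backend.velocities(positions, f_el)[constrained_nodes]

    if getattr(backend, "is_diagonal", False):
        f_ext = backend.gamma * (v_imposed - v0)
    else:
        c = len(constrained_nodes)
        M = mobility if mobility is not None else constrained_mobility(
            positions, backend, constrained_nodes
        )
        rhs = (v_imposed - v0).ravel()
        try:
            f_ext = np.linalg.solve(M, rhs).reshape(c, dim)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"constrained solve failed: {exc}") from exc
        if not np.all(np.isfinite(f_ext)):
            raise RuntimeError("constrained solve produced non-finite forces")

    scalar = float(np.sum(f_ext @ direction)) if direction is not None else None
    return f_ext, scalar


def _auto_dt(backend, positions, params, probe_node, record_interval):
    gamma = backend.effective_gamma(positions, probe_node=probe_node)
    k_max = max(params.k_max, 1e-30)
    return min(0.1 * gamma / k_max, record_interval, 1.0)


def run_pull_experiment(
    mesh,
    params: ElasticParams,
    backend,
    protocol: PullProtocol,
    record_interval: float = 1.0,
    snapshot_interval: float = 5.0,
    dt: float | None = None,
    max_dt_halvings: int = 4,
    corotate: bool = True,
    mobility_refresh: float = 1.0,
) -> SimulationRecord:
    """Run the three-phase pulling experiment and record force and displacement.

    During loading and holding the pulled edge's nodes follow the imposed
    trajectory exactly (they are re-pinned after each step); the recorded
    force is the Lagrange-multiplier constraint force projected on the pull
    direction.  During unloading the external force is zero.
    """
    edge = protocol.pulled_edge or mesh.pull_edge
    cons = np.asarray(edge, dtype=int)
    direction = protocol.direction(mesh.nodes.shape[1])

    dt0 = dt or _auto_dt(backend, mesh.nodes, params, int(cons[0]), record_interval)
    last_err: InstabilityError | None = None
    for attempt in range(max_dt_halvings + 1):
        try:
            return _run_phases(
                mesh, params, backend, protocol, cons, direction,
                dt0 / 2**attempt, record_interval, snapshot_interval, corotate,
                mobility_refresh,
            )
        except InstabilityError as err:
            last_err = err
    raise last_err


def _run_phases(
    mesh, params, backend, protocol, cons, direction, dt,
    record_interval, snapshot_interval, corotate, mobility_refresh=1.0,
):
    pos = mesh.nodes.copy()
    ref = mesh.nodes
    x0_cons = pos[cons].copy()
    mid0 = x0_cons.mean(axis=0)
    k = spring_k_array(mesh, params)

    times, disps, forces, phases = [], [], [], []
    disps_cor = []
    snapshots = {}
    t = 0.0

    def measured_disp(p):
        return float((p[cons].mean(axis=0) - mid0) @ direction)

    def corotated_disp(p):
        if not corotate:
            return measured_disp(p)
        mapped = kabsch_displacement(ref, p, p[cons])
        return float((mapped.mean(axis=0) - mid0) @ direction)

    def record(phase, applied):
        times.append(t)
        disps.append(measured_disp(pos))
        disps_cor.append(corotated_disp(pos))
        forces.append(applied)
        phases.append(phase)

    def maybe_snapshot():
        if snapshot_interval and (
            len(snapshots) == 0 or t - max(snapshots) >= snapshot_interval - 1e-9
        ):
            snapshots[round(t, 9)] = pos.copy()

    min_L0 = float(np.min(mesh.rest_lengths))

    diagonal = getattr(backend, "is_diagonal", False)
    mob_state = {"M": None, "t": -np.inf}

    def mobility_for(pos_now):
        # the constrained mobility varies slowly with configuration; refresh
        # it on a coarser cadence than the time step (exact for diagonal drag)
        if diagonal:
            return None
        if mob_state["M"] is None or t - mob_state["t"] >= mobility_refresh - 1e-12:
            mob_state["M"] = constrained_mobility(pos_now, backend, cons)
            mob_state["t"] = t
        return mob_state["M"]

    def run_phase(phase, duration, v_imp):
        nonlocal pos, t
        if duration <= 0:
            return
        n_steps = max(1, int(round(duration / dt)))
        dt_eff = duration / n_steps
        next_record = t + record_interval
        for _ in range(n_steps):
            if v_imp is not None:
                f_ext, scalar = constraint_force(
                    pos, mesh, params, backend, cons, v_imp, direction,
                    mobility=mobility_for(pos),
                )
                f = spring_forces(pos, mesh.edges, mesh.rest_lengths, k)
                f[cons] += f_ext
                applied = scalar
            else:
                f = spring_forces(pos, mesh.edges, mesh.rest_lengths, k)
                applied = 0.0
            v = backend.velocities(pos, f)
            step_vec = v * dt_eff
            if np.max(np.linalg.norm(step_vec, axis=1)) > 0.5 * min_L0:
                raise InstabilityError(
                    f"instability during {phase} at t={t:.3f}s (dt={dt_eff:.4g})",
                    record=_make_record(),
                )
            pos = pos + step_vec
            t += dt_eff
            if v_imp is not None:
                # pin the constrained nodes on the imposed trajectory exactly
                offset = _imposed_offset(t)
                pos[cons] = x0_cons + offset * direction
            if t >= next_record - 1e-9:
                record(phase, applied)
                maybe_snapshot()
                next_record += record_interval

    load_T = protocol.loading_duration

    def _imposed_offset(time):
        if time <= load_T:
            return protocol.loading_speed * time
        return protocol.loading_speed * load_T

    def _make_record():
        rec = SimulationRecord(
            times=np.asarray(times),
            displacement=np.asarray(disps),
            force=np.asarray(forces),
            phase=np.asarray(phases, dtype=object),
            snapshots=snapshots,
            extras={"displacement_corotated": np.asarray(disps_cor)},
            meta={
                "dt": dt,
                "protocol": protocol,
                "params": params,
                "pulled_edge": tuple(int(c) for c in cons),
            },
        )
        return rec

    record(LOADING, 0.0)
    maybe_snapshot()
    v_load = protocol.loading_speed * direction
    run_phase(LOADING, protocol.loading_duration, v_load)
    # override recorded displacements during loading with the imposed ramp
    for i, (ti, ph) in enumerate(zip(times, phases)):
        if ph == LOADING:
            disps[i] = protocol.loading_speed * min(ti, load_T)
    run_phase(HOLDING, protocol.holding_duration, np.zeros_like(direction))
    for i, ph in enumerate(phases):
        if ph == HOLDING:
            disps[i] = protocol.loading_speed * load_T
    run_phase(UNLOADING, protocol.unloading_duration, None)
    return _make_record()


def release_and_relax(
    positions: np.ndarray,
    mesh,
    params: ElasticParams,
    backend,
    duration: float,
    record_interval: float = 1.0,
    dt: float | None = None,
    corotate: bool = True,
    max_dt_halvings: int = 6,
) -> SimulationRecord:
    """Free relaxation from a given state, recording pulled-edge displacement decay."""
    proto = PullProtocol(
        loading_duration=1e-9, loading_speed=1e-9, holding_duration=0.0,
        unloading_duration=duration,
    )
    cons = np.asarray(mesh.pull_edge, dtype=int)
    direction = np.array([1.0, 0.0, 0.0])[: positions.shape[1]]
    dt = dt or _auto_dt(backend, positions, params, int(cons[0]), record_interval)
    pos = positions.copy()
    ref = mesh.nodes
    mid0 = ref[cons].mean(axis=0)
    k = spring_k_array(mesh, params)
    min_L0 = float(np.min(mesh.rest_lengths))

    times, disps, disps_cor = [0.0], [], []

    def measure():
        disps.append(float((pos[cons].mean(axis=0) - mid0) @ direction))
        if corotate:
            mapped = kabsch_displacement(ref, pos, pos[cons])
            disps_cor.append(float((mapped.mean(axis=0) - mid0) @ direction))
        else:
            disps_cor.append(disps[-1])

    measure()
    t = 0.0
    next_rec = record_interval
    n_steps = max(1, int(round(duration / dt)))
    dt_eff = duration / n_steps
    halvings = 0
    step_i = 0
    while step_i < n_steps:
        f = spring_forces(pos, mesh.edges, mesh.rest_lengths, k)
        v = backend.velocities(pos, f)
        step = v * dt_eff
        if np.max(np.linalg.norm(step, axis=1)) > 0.5 * min_L0:
            if halvings >= max_dt_halvings:
                raise InstabilityError(f"instability during relaxation at t={t:.3f}s")
            halvings += 1
            n_steps = (n_steps - step_i) * 2 + step_i
            dt_eff /= 2.0
            continue
        pos = pos + step
        t += dt_eff
        step_i += 1
        if t >= next_rec - 1e-9:
            times.append(t)
            measure()
            next_rec += record_interval

    n = len(times)
    return SimulationRecord(
        times=np.asarray(times),
        displacement=np.asarray(disps[:n]),
        force=np.zeros(n),
        phase=np.asarray([UNLOADING] * n, dtype=object),
        extras={"displacement_corotated": np.asarray(disps_cor[:n])},
        meta={"dt": dt, "params": params},
    )
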