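"""Measurement procedures: kymographs, deformation profiles, collapse
exponents, exponential decay fits, maximal force and recoil.

These operate interchangeably on synthetic membrane movies (space-time
intensity stacks) and on simulation records, mirroring how the same
quantities are extracted from microscopy and from the model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .records import LOADING, SimulationRecord


@dataclass
class Kymograph:
    """Space-time representation of membrane positions along a sampling curve.

    ``traces[t, m]`` is the arc-length position (um) of membrane m at frame
    t; ``intensity`` (optional) is the raw intensity matrix sampled along
    the curve; ``lost[m]`` flags traces whose tracking gap exceeded the
    threshold (they are flagged, never silently interpolated).
    """

    times: np.ndarray  # (T,)
    traces: np.ndarray  # (T, M) arc positions, um
    intensity: np.ndarray | None = None  # (T, n_samples)
    arc_axis: np.ndarray | None = None  # (n_samples,) arc coordinate of samples
    lost: np.ndarray | None = None  # (M,) bool

    @property
    def n_membranes(self) -> int:
        return self.traces.shape[1]


@dataclass
class DeformationProfile:
    """Displacement of each membrane from its initial position vs that position."""

    initial_positions: np.ndarray  # (M,)
    displacement: np.ndarray  # (M,)
    time: float


@dataclass
class DecayFit:
    """Exponential decay fit d(t) = A exp(-t/tau) + asymptote."""

    tau: float
    asymptote: float
    window: tuple
    r2: float


@dataclass
class CollapseResult:
    """Rescaling exponents of a deformation-profile family.

    Profiles collapse when plotted as d / t^alpha versus x / t^beta; beta = 0
    means y-rescaling alone collapses the family (adiabatic, friction-free
    spreading), while beta around 0.5 indicates diffusive spreading driven by
    external friction.
    """

    alpha: float | None
    beta: float
    residual: float


# ---------------------------------------------------------------------------
# kymograph extraction


def _track_peaks(times, peak_lists, max_jump, max_gap_frames=3):
    """Nearest-neighbour membrane tracking with minimal-displacement tie-break."""
    m = len(peak_lists[0])
    traces = np.full((len(peak_lists), m), np.nan)
    traces[0] = np.sort(np.asarray(peak_lists[0], dtype=float))
    gaps = np.zeros(m, dtype=int)
    lost = np.zeros(m, dtype=bool)
    for ti in range(1, len(peak_lists)):
        peaks = np.asarray(peak_lists[ti], dtype=float)
        prev = traces[ti - 1].copy()
        assigned = np.full(m, np.nan)
        if len(peaks):
            # greedy assignment ordered by displacement (minimal total movement)
            pairs = [
                (abs(p - prev[j]), j, pi)
                for j in range(m)
                if np.isfinite(prev[j])
                for pi, p in enumerate(peaks)
                if abs(p - prev[j]) <= max_jump
            ]
            pairs.sort()
            used_j, used_p = set(), set()
            for d, j, pi in pairs:
                if j in used_j or pi in used_p:
                    continue
                used_j.add(j)
                used_p.add(pi)
                assigned[j] = peaks[pi]
        for j in range(m):
            if np.isfinite(assigned[j]):
                traces[ti, j] = assigned[j]
                gaps[j] = 0
            else:
                traces[ti, j] = prev[j]  # carried, counted as a gap
                gaps[j] += 1
                if gaps[j] > max_gap_frames:
                    lost[j] = True
    return traces, lost


def kymograph_from_movie(
    movie: np.ndarray,
    times: np.ndarray | None = None,
    sampling_row: int | None = None,
    sampling_curve: np.ndarray | None = None,
    pixel_size: float = 1.0,
    max_jump: float = 2.0,
    min_prominence: float | None = None,
) -> Kymograph:
    """Extract membrane traces from a (T, H, W) intensity movie.

    The sampling curve defaults to the central image row; a general curve is
    given as (P, 2) pixel coordinates (row, col).  Membrane positions are
    intensity peaks along the curve, refined to sub-pixel accuracy by
    parabolic interpolation and tracked across frames by nearest-neighbour
    continuity (maximum jump ``max_jump`` um per frame).
    """
    movie = np.asarray(movie, dtype=float)
    T = movie.shape[0]
    if times is None:
        times = np.arange(T, dtype=float)
    if sampling_curve is None:
        row = movie.shape[1] // 2 if sampling_row is None else sampling_row
        profiles = movie[:, row, :]
        arc = np.arange(movie.shape[2]) * pixel_size
    else:
        curve = np.asarray(sampling_curve, dtype=float)
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1) * pixel_size
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        profiles = np.stack(
            [map_coordinates(frame, curve.T, order=1, mode="nearest") for frame in movie]
        )
    if min_prominence is None:
        min_prominence = 0.2 * (profiles.max() - profiles.min())

    peak_lists = []
    for prof in profiles:
        idx, _ = find_peaks(prof, prominence=min_prominence)
        # parabolic sub-pixel refinement
        pos = []
        for i in idx:
            if 0 < i < len(prof) - 1:
                denom = prof[i - 1] - 2 * prof[i] + prof[i + 1]
                shift = 0.5 * (prof[i - 1] - prof[i + 1]) / denom if denom != 0 else 0.0
                pos.append(np.interp(i + shift, np.arange(len(arc)), arc))
            else:
                pos.append(arc[i])
        peak_lists.append(pos)

    traces, lost = _track_peaks(times, peak_lists, max_jump=max_jump)
    return Kymograph(times=times, traces=traces, intensity=profiles, arc_axis=arc, lost=lost)


def traces_from_embryo_record(
    mesh,
    record: SimulationRecord,
    band_fraction: float = 0.25,
    corotate: bool = True,
) -> Kymograph:
    """Membrane traces along the sagittal mid-layer curve of the embryo.

    Apical tiling vertices within a band around the sagittal plane (y = 0)
    act as the fluorescent membrane marks; their positions are projected to
    arc length along the sagittal ellipse.  With ``corotate`` the snapshots
    are first mapped into the best-fit rigid-body frame, mirroring the shell
    anchoring of the full fluid model.
    """
    from .pull_protocol import kabsch_displacement

    if not record.snapshots:
        raise ValueError("record carries no node snapshots")
    a_s = mesh.spec.a_surface
    b_s = mesh.spec.b_surface
    V = mesh.apical_vertex_count
    ref = mesh.nodes
    band = band_fraction * b_s
    sel = np.where(np.abs(ref[:V, 1]) < band)[0]

    def arc_coord(p):
        # elliptic angle, scaled to arc length via local ellipse metric
        th = np.arctan2(p[:, 2] / b_s, p[:, 0] / a_s)
        return th

    # convert angles to approximate arc length along the sagittal ellipse
    th_grid = np.linspace(-np.pi, np.pi, 2001)
    ds = np.sqrt((a_s * np.sin(th_grid)) ** 2 + (b_s * np.cos(th_grid)) ** 2)
    s_grid = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(th_grid))])

    def to_arc(th):
        return np.interp(th, th_grid, s_grid)

    snap_times = np.array(sorted(record.snapshots))
    traces = np.empty((len(snap_times), len(sel)))
    for i, t in enumerate(snap_times):
        pos = record.snapshots[t]
        pts = kabsch_displacement(ref, pos, pos[sel]) if corotate else pos[sel]
        traces[i] = to_arc(arc_coord(pts))
    order = np.argsort(traces[0])
    return Kymograph(
        times=snap_times,
        traces=traces[:, order],
        lost=np.zeros(len(sel), dtype=bool),
    )


def make_kymograph(source, sampling_curve=None, **kw) -> Kymograph:
    """Dispatch: movie array -> peak tracking; simulation record -> mesh traces."""
    if isinstance(source, SimulationRecord):
        mesh = kw.pop("mesh", None)
        if mesh is None:
            raise ValueError("pass mesh=... to build a kymograph from a record")
        return traces_from_embryo_record(mesh, source, **kw)
    return kymograph_from_movie(np.asarray(source), sampling_curve=sampling_curve, **kw)


# ---------------------------------------------------------------------------
# deformation profiles and collapse


def deformation_profiles(kymo: Kymograph, times) -> list:
    """Displacement of each membrane from its initial position, per time point."""
    profiles = []
    for t in np.atleast_1d(times):
        i = int(np.argmin(np.abs(kymo.times - t)))
        profiles.append(
            DeformationProfile(
                initial_positions=kymo.traces[0].copy(),
                displacement=kymo.traces[i] - kymo.traces[0],
                time=float(kymo.times[i]),
            )
        )
    return profiles


def normalize_profiles(profiles):
    """Scale each profile so its maximal |displacement| is 1; report the
    residual spread of the normalized family (0 for an exactly self-similar
    family)."""
    scaled = []
    for p in profiles:
        peak = np.max(np.abs(p.displacement))
        scale = peak if peak > 0 else 1.0
        scaled.append(
            DeformationProfile(
                initial_positions=p.initial_positions,
                displacement=p.displacement / scale,
                time=p.time,
            )
        )
    residual = _family_residual(
        [(p.initial_positions, p.displacement) for p in scaled]
    )
    return scaled, CollapseResult(alpha=None, beta=0.0, residual=residual)


def _family_residual(curves, n_grid: int = 101) -> float:
    """Mean pointwise std of curves interpolated onto their common support."""
    if len(curves) < 2:
        return 0.0
    lo = max(np.min(x) for x, _ in curves)
    hi = min(np.max(x) for x, _ in curves)
    if hi <= lo:
        return np.inf
    grid = np.linspace(lo, hi, n_grid)
    vals = []
    for x, y in curves:
        order = np.argsort(x)
        vals.append(np.interp(grid, x[order], y[order]))
    vals = np.asarray(vals)
    return float(np.mean(np.std(vals, axis=0)))


def estimate_beta(
    profiles,
    beta_range=(-0.2, 1.0),
    beta_step: float = 0.01,
    origin: float | None = None,
) -> CollapseResult:
    """Spatial rescaling exponent from a deformation-profile family.

    For each candidate beta the x-axis is rescaled by t^-beta (about the
    point of maximal displacement) and the y-axis normalized to unit peak;
    beta minimizing the residual spread wins, then a 10x finer local grid
    refines it.  alpha comes from the log-log slope of the peak displacement
    versus time.
    """
    usable = [p for p in profiles if np.max(np.abs(p.displacement)) > 0 and p.time > 0]
    if len(usable) < 3:
        raise ValueError("need at least 3 non-degenerate profiles")
    if origin is None:
        p0 = usable[-1]
        origin = float(p0.initial_positions[np.argmax(np.abs(p0.displacement))])

    def curves_for(beta):
        out = []
        for p in usable:
            xi = (p.initial_positions - origin) / p.time**beta
            y = np.abs(p.displacement) / np.max(np.abs(p.displacement))
            out.append((xi, y))
        return out

    def residual(beta):
        return _family_residual(curves_for(beta))

    grid = np.arange(beta_range[0], beta_range[1] + beta_step / 2, beta_step)
    res = np.array([residual(b) for b in grid])
    best = grid[int(np.argmin(res))]
    fine = np.arange(best - beta_step, best + beta_step, beta_step / 10)
    res_fine = np.array([residual(b) for b in fine])
    beta_hat = float(fine[int(np.argmin(res_fine))])

    peaks = np.array([np.max(np.abs(p.displacement)) for p in usable])
    ts = np.array([p.time for p in usable])
    alpha = float(np.polyfit(np.log(ts), np.log(peaks), 1)[0])
    return CollapseResult(alpha=alpha, beta=beta_hat, residual=float(np.min(res_fine)))


# ---------------------------------------------------------------------------
# decay fitting, force, recoil


def fit_decay(
    times: np.ndarray,
    values: np.ndarray,
    asymptote_fraction: float = 0.1,
    noise_multiple: float = 3.0,
) -> DecayFit:
    """Exponential decay constant from the asymptote-subtracted log-linear slope.

    The asymptote is the mean of the final ``asymptote_fraction`` of the
    trace; after subtraction, a least-squares line is fitted to log(signal)
    over the window where the signal exceeds ``noise_multiple`` times the
    tail noise.  Invariant to adding a constant and to uniform rescaling.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 10:
        raise ValueError("need at least 10 samples to fit a decay")
    n_tail = max(3, int(round(asymptote_fraction * len(values))))
    tail = values[-n_tail:]
    asymptote = float(tail.mean())
    y = values - asymptote
    noise = float(tail.std())
    floor = max(noise_multiple * noise, 1e-12 * max(abs(y[0]), 1.0))

    mask = y > floor
    if mask.sum() < 3:
        # shrink the floor once for very clean traces
        floor = 1e-9 * max(abs(y[0]), 1e-30)
        mask = y > floor
    # use the contiguous window from the start
    end = int(np.argmax(~mask)) if (~mask).any() else len(y)
    if end < 3:
        raise ValueError("decay window too short after asymptote subtraction")
    yw, tw = y[:end], times[:end]
    if np.any(yw <= 0):
        warnings.warn("non-positive values inside decay window; shrinking window")
        end = int(np.argmax(yw <= 0))
        yw, tw = y[:end], times[:end]
        if end < 3:
            raise ValueError("decay window collapsed")
    slope, intercept = np.polyfit(tw, np.log(yw), 1)
    if slope >= 0:
        raise ValueError("trace does not decay")
    pred = slope * tw + intercept
    ss_res = np.sum((np.log(yw) - pred) ** 2)
    ss_tot = np.sum((np.log(yw) - np.log(yw).mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    tau = -1.0 / slope

    # the tail mean overestimates the asymptote on traces that have not fully
    # plateaued; refine (A, tau, C) by nonlinear least squares from the
    # log-linear initialization
    from scipy.optimize import curve_fit

    try:
        popt, _ = curve_fit(
            lambda t, A, tau_, C: A * np.exp(-t / tau_) + C,
            times, values,
            p0=(float(np.exp(intercept)), float(tau), asymptote),
            maxfev=10000,
        )
        if popt[1] > 0:
            tau, asymptote = float(popt[1]), float(popt[2])
    except RuntimeError:
        pass  # keep the log-linear estimate
    return DecayFit(
        tau=float(tau),
        asymptote=float(asymptote),
        window=(float(tw[0]), float(tw[-1])),
        r2=float(r2),
    )


def max_force(record: SimulationRecord) -> float:
    """Maximal applied force (nN); for a monotone loading ramp this is the
    force at the end of loading."""
    return float(np.max(record.force)) if len(record.force) else 0.0


def recoil_fraction(record: SimulationRecord) -> float:
    """Fraction of the peak pulled-edge displacement recovered by the end of
    unloading (drift-corrected series used when available)."""
    disp = record.extras.get("displacement_corotated", record.displacement)
    peak = float(np.max(np.abs(disp)))
    if peak <= 0:
        return 0.0
    final = float(abs(disp[-1]))
    return 1.0 - final / peak
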