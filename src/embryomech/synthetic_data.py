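"""Synthetic fixtures with known ground truth.

Emulates the raw data the quantification and calibration stages consume:
fluorescent membrane movies displaced by a spatially decaying, temporally
growing deformation field; cantilever deflection-vs-time series; and noisy
exponential relaxation traces.  Every generator is seeded and stores (or
returns) the exact truth it rendered, so recovery can be tested end to end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cantilever_calibration import CantileverSpec, deflection_under_drag


@dataclass(frozen=True)
class SyntheticTruth:
    """Parameters of the planted displacement field d(x, t).

    d(x, t) = amplitude * t^alpha * exp(-|x - x0| / (decay_length * t^beta)),
    evaluated at the membranes' initial positions.  ``membrane_spacing``
    emulates the ~8 um cell size; ``noise`` is the additive Gaussian
    intensity noise of the rendered movie (fraction of peak intensity).
    """

    amplitude: float = 0.3
    alpha: float = 1.0
    beta: float = 0.0
    decay_length: float = 40.0
    pull_position: float = 0.0
    membrane_spacing: float = 8.0
    noise: float = 0.02
    seed: int = 0

    def displacement(self, x, t):
        x = np.asarray(x, dtype=float)
        if t <= 0:
            return np.zeros_like(x)
        lam = self.decay_length * (t**self.beta if self.beta != 0 else 1.0)
        return self.amplitude * t**self.alpha * np.exp(-np.abs(x - self.pull_position) / lam)


def membrane_positions(truth: SyntheticTruth, field_length: float) -> np.ndarray:
    """Initial membrane positions spanning [0, field_length] at the truth spacing."""
    return np.arange(0.0, field_length + truth.membrane_spacing / 2, truth.membrane_spacing)


def synth_pull_movie(
    truth: SyntheticTruth,
    n_frames: int = 20,
    field_length: float = 160.0,
    frame_interval: float = 3.0,
    pixel_size: float = 0.5,
    height: int = 16,
    line_sigma: float = 1.0,
    margin: float = 5.0,
):
    """Render a (T, H, W) membrane movie plus the true trajectories.

    Membranes are Gaussian-profile bright lines at x_i + d(x_i, t) with
    additive Gaussian intensity noise; the returned ``trajectories`` array
    (T, M) is the exact truth in image arc coordinates (a ``margin`` um pad
    keeps every membrane away from the image border), recoverable by the
    kymograph pipeline.
    """
    rng = np.random.default_rng(truth.seed)
    x0 = membrane_positions(truth, field_length)
    times = np.arange(n_frames) * frame_interval
    width = int(round((field_length + 2 * margin) / pixel_size)) + 1
    xs = np.arange(width) * pixel_size  # image arc coordinate

    trajectories = np.stack(
        [x0 + truth.displacement(x0, t) for t in times]
    ) + margin
    movie = np.zeros((n_frames, height, width))
    for ti in range(n_frames):
        profile = np.zeros(width)
        for xm in trajectories[ti]:
            profile += np.exp(-0.5 * ((xs - xm) / line_sigma) ** 2)
        movie[ti] = profile[None, :]
    movie += truth.noise * rng.standard_normal(movie.shape)
    return movie, times, trajectories


def synth_profile_family(
    truth: SyntheticTruth,
    times,
    field_length: float = 160.0,
):
    """Noise-free deformation-profile family straight from the truth field."""
    from .quantification import DeformationProfile

    x0 = membrane_positions(truth, field_length)
    return [
        DeformationProfile(
            initial_positions=x0.copy(),
            displacement=truth.displacement(x0, t),
            time=float(t),
        )
        for t in times
    ]


def synth_deflection_series(
    spec: CantileverSpec,
    fluid_viscosity: float,
    speed: float,
    duration: float = 30.0,
    dt: float = 0.1,
    rise_time: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
):
    """Cantilever tip deflection while dragged at fixed speed: exponential
    approach to the steady-state drag deflection, plus seeded noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    plateau = deflection_under_drag(spec, fluid_viscosity, speed)
    clean = plateau * (1.0 - np.exp(-t / rise_time))
    return t, clean + noise * plateau * rng.standard_normal(len(t)), plateau


def synth_relaxation_trace(
    tau: float,
    asymptote: float = 0.0,
    amplitude: float = 1.0,
    noise: float = 0.0,
    n: int = 200,
    duration: float | None = None,
    seed: int = 0,
):
    """Noisy exponential decay A exp(-t/tau) + C as a fixture for decay fitting."""
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = 5.0 * tau
    t = np.linspace(0.0, duration, n)
    clean = amplitude * np.exp(-t / tau) + asymptote
    return t, clean + noise * amplitude * rng.standard_normal(n)
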