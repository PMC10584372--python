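"""PDMS cantilever beam mechanics: deflection <-> force, drag calibration.

The flexible tip is a clamped-free Euler-Bernoulli beam.  A point load at the
tip gives F = 3 E I d / L^3; a uniform distributed load (viscous drag per
unit length while the probe is dragged through a calibration fluid) gives a
tip deflection d = w L^4 / (8 E I).  Dragging at known speed through a fluid
of known viscosity therefore inverts to the Young's modulus of the polymer.

Units: lengths um, forces nN, E in MPa (1 MPa = 1e3 nN/um^2), viscosity in
nN s/um^2, speed um/s.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

MPA_TO_NN_PER_UM2 = 1.0e3

#: slender-body drag constant for a cylinder moving perpendicular to its axis
SLENDER_BODY_CONSTANT = 0.84


@dataclass(frozen=True)
class CantileverSpec:
    """Exposed flexible tip geometry plus material modulus.

    ``cross_section`` is ("circular", radius) or
    ("rectangular", width, thickness) with the thickness in the bending
    direction.  ``youngs_modulus_MPa`` may be None while calibrating.
    """

    tip_length: float  # um, exposed flexible portion
    cross_section: tuple
    youngs_modulus_MPa: float | None = 2.1

    def __post_init__(self) -> None:
        if self.tip_length <= 0:
            raise ValueError("tip_length must be > 0")
        kind = self.cross_section[0]
        dims = self.cross_section[1:]
        if any(d <= 0 for d in dims):
            raise ValueError("cross-section dimensions must be > 0")
        if kind not in ("circular", "rectangular"):
            raise ValueError(f"unknown cross-section {kind!r}")
        if kind == "circular" and len(dims) != 1:
            raise ValueError("circular section takes (radius,)")
        if kind == "rectangular" and len(dims) != 2:
            raise ValueError("rectangular section takes (width, thickness)")
        if self.youngs_modulus_MPa is not None and self.youngs_modulus_MPa <= 0:
            raise ValueError("Young's modulus must be > 0")

    @property
    def second_moment(self) -> float:
        """Second moment of area I (um^4) about the bending axis."""
        kind = self.cross_section[0]
        if kind == "circular":
            (r,) = self.cross_section[1:]
            return np.pi * r**4 / 4.0
        w, t = self.cross_section[1:]
        return w * t**3 / 12.0

    @property
    def effective_radius(self) -> float:
        """Radius used in the slender-body drag logarithm."""
        kind = self.cross_section[0]
        if kind == "circular":
            return self.cross_section[1]
        w, t = self.cross_section[1:]
        return 0.5 * np.sqrt(w * t)  # area-equivalent radius

    @property
    def EI(self) -> float:
        if self.youngs_modulus_MPa is None:
            raise ValueError("Young's modulus not set on this spec")
        return self.youngs_modulus_MPa * MPA_TO_NN_PER_UM2 * self.second_moment

    def with_modulus(self, E_MPa: float) -> "CantileverSpec":
        return replace(self, youngs_modulus_MPa=E_MPa)


def force_from_deflection(spec: CantileverSpec, tip_deflection: float) -> float:
    """Force (nN) at the tip from the observed tip deflection (um).

    Clamped-free beam with a point tip load: F = 3 E I d / L^3, strictly
    linear in the deflection.  Warns outside the small-deflection regime
    (deflection above 20% of the tip length).
    """
    if abs(tip_deflection) > 0.2 * spec.tip_length:
        warnings.warn(
            "tip deflection exceeds 20% of the tip length; the linear "
            "beam relation becomes inaccurate"
        )
    return 3.0 * spec.EI * tip_deflection / spec.tip_length**3


def deflection_under_point_load(spec: CantileverSpec, force: float) -> float:
    """Inverse of `force_from_deflection` (um)."""
    return force * spec.tip_length**3 / (3.0 * spec.EI)


def drag_per_length(
    spec: CantileverSpec,
    fluid_viscosity: float,
    speed: float,
    slender_constant: float = SLENDER_BODY_CONSTANT,
) -> float:
    """Slender-body viscous load w (nN/um) on a cylinder dragged sideways."""
    L, r = spec.tip_length, spec.effective_radius
    return 4.0 * np.pi * fluid_viscosity * speed / (np.log(L / r) + slender_constant)


def deflection_under_drag(
    spec: CantileverSpec,
    fluid_viscosity: float,
    speed: float,
    slender_constant: float = SLENDER_BODY_CONSTANT,
) -> float:
    """Steady-state tip deflection (um) while dragged at constant speed.

    Uniformly distributed load on a clamped-free beam: d = w L^4 / (8 E I);
    linear in both the speed and the viscosity.
    """
    w = drag_per_length(spec, fluid_viscosity, speed, slender_constant)
    return w * spec.tip_length**4 / (8.0 * spec.EI)


def estimate_modulus_from_drag(
    spec: CantileverSpec,
    fluid_viscosity: float,
    speed: float,
    measured_deflection: float,
    slender_constant: float = SLENDER_BODY_CONSTANT,
) -> float:
    """Young's modulus (MPa) from a drag-calibration measurement.

    Exact inverse of `deflection_under_drag` for the modulus: halving the
    measured deflection doubles the estimate.
    """
    if measured_deflection <= 0:
        raise ValueError("measured deflection must be > 0")
    w = drag_per_length(spec, fluid_viscosity, speed, slender_constant)
    EI = w * spec.tip_length**4 / (8.0 * measured_deflection)
    return EI / (spec.second_moment * MPA_TO_NN_PER_UM2)


def deflection_profile_numeric(
    spec: CantileverSpec,
    load_per_length=None,
    tip_force: float = 0.0,
    n: int = 20001,
    segments=None,
):
    """Numerical Euler-Bernoulli integration for a clamped-free beam.

    Integrates the bending-moment distribution twice (cumulative trapezoid)
    for an arbitrary distributed load ``load_per_length(x)`` plus an optional
    tip point force.  ``segments`` optionally lists (x_start, x_end, EI)
    pieces for tapered (piecewise-constant cross-section) cantilevers;
    default is the uniform EI of the spec.  Returns (x, deflection).
    """
    L = spec.tip_length
    x = np.linspace(0.0, L, n)
    q = np.zeros_like(x) if load_per_length is None else np.asarray(
        [load_per_length(xi) for xi in x], dtype=float
    )
    # shear V(x) = tip_force + integral_x^L q ; moment M(x) = integral_x^L V
    def _revcumtrap(y):
        dx = x[1] - x[0]
        c = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * dx)])
        return c[-1] - c

    V = tip_force + _revcumtrap(q)
    M = _revcumtrap(V)
    if segments is None:
        EI = np.full_like(x, spec.EI)
    else:
        EI = np.empty_like(x)
        for (xs, xe, ei) in segments:
            EI[(x >= xs) & (x <= xe)] = ei
    curv = M / EI
    dx = x[1] - x[0]
    slope = np.concatenate([[0.0], np.cumsum(0.5 * (curv[1:] + curv[:-1]) * dx)])
    defl = np.concatenate([[0.0], np.cumsum(0.5 * (slope[1:] + slope[:-1]) * dx)])
    return x, defl
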