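"""Spiral-channel geometry, local cross-section frame and dimensionless groups.

The channel is an Archimedean spiral of rectangular cross-section.  ``w`` is
the in-plane (radial) dimension, ``h`` the out-of-plane (axis-of-curvature)
dimension.  The centerline radius grows linearly with the accumulated angle,
``R(theta) = r0 + pitch * theta / (2 pi)`` with ``pitch = w + s_gap`` (the
turn spacing ``s_gap`` is the wall-to-wall gap between adjacent turns).

All quantities are SI internally.  The local cross-section frame is
``(xi, zeta)``: ``xi`` is the lateral offset from the centerline, positive
toward the *outer* (larger-radius) wall, ``zeta`` the offset from the
mid-plane along the spiral axis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "OutOfChannelError",
    "FluidProps",
    "ParticleSpec",
    "ChannelSpec",
    "WATER",
    "make_channel",
    "hydraulic_diameter",
    "centerline_radius",
    "channel_reynolds",
    "characteristic_velocity",
    "dean_number",
    "to_local",
    "from_local",
]


class GeometryError(ValueError):
    """Invalid channel, fluid or particle geometry."""


class OutOfChannelError(ValueError):
    """A queried position lies outside the channel."""


@dataclass(frozen=True)
class FluidProps:
    """Continuous-phase properties.

    Parameters
    ----------
    density : float
        Fluid density ``rho_f`` in kg/m^3.
    viscosity : float
        Dynamic viscosity ``mu`` in Pa s.
    """

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.viscosity > 0):
            raise GeometryError("fluid density and viscosity must be positive")


#: Water at the round-number values that reproduce the channel Reynolds
#: numbers quoted for the study cases (rho = 1000 kg/m^3, mu = 1 mPa s).
WATER = FluidProps(density=1000.0, viscosity=1.0e-3)


@dataclass(frozen=True)
class ParticleSpec:
    """A rigid spherical particle.

    ``radius`` in m, ``density`` in kg/m^3; the mass is derived.
    """

    radius: float
    density: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.density > 0):
            raise GeometryError("particle radius and density must be positive")

    @property
    def mass(self) -> float:
        """Particle mass ``(4/3) pi Rp^3 rho_p`` in kg."""
        return 4.0 / 3.0 * math.pi * self.radius**3 * self.density


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular-cross-section Archimedean spiral channel.

    Parameters
    ----------
    width, height : float
        Cross-section dimensions in m (``width`` is radial/in-plane).
    r0 : float
        Centerline radius at the inlet, m.
    turn_spacing : float
        Wall-to-wall gap between adjacent turns, m.
    n_turns : int
        Number of full turns; the outlet sits at ``theta = 2 pi n_turns``.
    """

    width: float
    height: float
    r0: float
    turn_spacing: float
    n_turns: int

    def __post_init__(self) -> None:
        if not (
            self.width > 0
            and self.height > 0
            and self.r0 > 0
            and self.turn_spacing > 0
        ):
            raise GeometryError("channel dimensions must be positive")
        if self.n_turns < 1:
            raise GeometryError("need at least one turn")
        if self.r0 <= self.width / 2:
            raise GeometryError("spiral start radius must exceed half the width")

    @property
    def hydraulic_diameter(self) -> float:
        """``Dh = 2 w h / (w + h)``, m."""
        return 2.0 * self.width * self.height / (self.width + self.height)

    @property
    def aspect_ratio(self) -> float:
        return max(self.width, self.height) / min(self.width, self.height)

    @property
    def pitch(self) -> float:
        """Centerline radial advance per turn, ``w + s_gap``."""
        return self.width + self.turn_spacing

    @property
    def theta_end(self) -> float:
        return 2.0 * math.pi * self.n_turns

    @property
    def area(self) -> float:
        return self.width * self.height


def make_channel(
    w: float, h: float, r0: float, s_gap: float, n_turns: int
) -> ChannelSpec:
    """Build a :class:`ChannelSpec`; raises :class:`GeometryError` on bad input."""
    return ChannelSpec(width=w, height=h, r0=r0, turn_spacing=s_gap, n_turns=n_turns)


def hydraulic_diameter(spec: ChannelSpec) -> float:
    return spec.hydraulic_diameter


def centerline_radius(spec: ChannelSpec, theta):
    """Centerline radius at accumulated angle ``theta`` (rad from the inlet).

    Valid for ``0 <= theta <= 2 pi n_turns``; anything else raises
    :class:`OutOfChannelError`.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > spec.theta_end + 1e-12):
        raise OutOfChannelError("theta outside the channel extent")
    r = spec.r0 + spec.pitch * th / (2.0 * math.pi)
    return float(r) if np.isscalar(theta) else r


def characteristic_velocity(spec: ChannelSpec, Q: float) -> float:
    """Velocity scale ``U = 1.5 Q / (w h)``.

    The 3/2 factor is the parallel-plate maximum-over-mean ratio; this is the
    convention under which the study cases' printed channel Reynolds numbers
    are reproduced, and it matches the ``U`` of the lift-coefficient scaling.
    """
    return 1.5 * Q / spec.area


def channel_reynolds(spec: ChannelSpec, fluid: FluidProps, Q: float) -> float:
    """Channel Reynolds number ``Re = rho U Dh / mu`` with ``U = 1.5 Q/(w h)``."""
    if Q < 0:
        raise GeometryError("flow rate must be non-negative")
    U = characteristic_velocity(spec, Q)
    return fluid.density * U * spec.hydraulic_diameter / fluid.viscosity


def dean_number(spec: ChannelSpec, fluid: FluidProps, Q: float, R: float) -> float:
    """Dean number ``De = Re sqrt(Dh / (2 R))`` at local centerline radius R."""
    if R <= 0:
        raise GeometryError("radius must be positive")
    Re = channel_reynolds(spec, fluid, Q)
    return Re * math.sqrt(spec.hydraulic_diameter / (2.0 * R))


def to_local(spec: ChannelSpec, r, theta, z, check: bool = True):
    """Map cylindrical ``(r, theta, z)`` to the local frame ``(xi, zeta)``."""
    R = centerline_radius(spec, theta)
    xi = np.asarray(r, dtype=float) - R
    zeta = np.asarray(z, dtype=float)
    if check:
        if np.any(np.abs(xi) > spec.width / 2 * (1 + 1e-12) + 1e-18) or np.any(
            np.abs(zeta) > spec.height / 2 * (1 + 1e-12) + 1e-18
        ):
            raise OutOfChannelError("position outside the cross-section")
    if np.isscalar(r) and np.isscalar(z):
        return float(xi), float(zeta)
    return xi, zeta


def from_local(spec: ChannelSpec, xi, zeta, theta):
    """Map local ``(xi, zeta)`` at angle ``theta`` back to ``(r, theta, z)``."""
    if np.any(np.abs(np.asarray(xi)) > spec.width / 2 * (1 + 1e-12)) or np.any(
        np.abs(np.asarray(zeta)) > spec.height / 2 * (1 + 1e-12)
    ):
        raise OutOfChannelError("position outside the cross-section")
    R = centerline_radius(spec, theta)
    r = R + np.asarray(xi, dtype=float)
    z = np.asarray(zeta, dtype=float)
    if np.isscalar(xi) and np.isscalar(zeta):
        return float(r), theta, float(z)
    return r, theta, z


def arc_length(spec: ChannelSpec, theta_to: float | None = None, n: int = 20001) -> float:
    """Centerline arc length from the inlet to ``theta_to`` by quadrature of
    ``sqrt(R^2 + (dR/dtheta)^2)``."""
    end = spec.theta_end if theta_to is None else theta_to
    th = np.linspace(0.0, end, n)
    R = spec.r0 + spec.pitch * th / (2.0 * math.pi)
    dR = spec.pitch / (2.0 * math.pi)
    return float(np.trapezoid(np.sqrt(R * R + dR * dR), th))
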