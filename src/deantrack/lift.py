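"""Inertial lift force fields over the channel cross-section.

Three interchangeable providers:

* :class:`SuperposedLift` — the plane-Poiseuille net lift coefficient applied
  independently per wall pair (each pair of opposite walls contributes a
  force normal to itself), the straightforward extension of the 2D
  matched-asymptotics result to a duct.  Its stable equilibria sit on the
  cross-section diagonals.
* :class:`HoodStyleLift` — a synthetic analytic field reproducing the
  topology of the 3D-Poiseuille asymptotic solution: stable points on the
  symmetry axes, diagonal saddles, unstable center.  This is a stand-in
  with the published solution's qualitative structure, not its actual
  coefficients.
* :class:`TabulatedLift` — bilinear interpolation of a lift table read from
  a plain-text file, for externally generated numerical lift data.

The plane-Poiseuille coefficient is a documented closed-form surrogate, a
cubic of the Ho-Leal matched-asymptotics type

    fL(s, Re) = C * s * (s_eq(Re)^2 - s^2)

odd in the position fraction ``s``, with zeros at 0 and the equilibrium
fraction ``s_eq(Re)``; ``s_eq -> 0.6`` at low Re (the classical annulus
position) and shifts toward the wall as Re grows.  The amplitude ``C = 22``
sets the peak coefficient to ~2.2 in the ``F Dh^2/(rho U^2 a^4)``
normalization, i.e. ~0.55 in the gap-squared normalization in which the
matched-asymptotics curves are usually plotted.

Forces follow ``F = fL * rho U^2 a^4 / Dh^2`` with ``U = 1.5 Q/(w h)``.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .flowfield import _bilinear
from .geometry import ChannelSpec, FluidProps, characteristic_velocity, channel_reynolds

__all__ = [
    "LIFT_AMPLITUDE",
    "equilibrium_fraction",
    "fL_plane_poiseuille",
    "SuperposedLift",
    "HoodStyleLift",
    "TabulatedLift",
    "save_lift_table",
    "load_lift_table",
    "EquilibriumPoint",
    "find_equilibria",
    "LiftTableError",
]

#: Amplitude of the plane-Poiseuille lift coefficient surrogate.
LIFT_AMPLITUDE = 22.0


class LiftTableError(ValueError):
    """Malformed or mismatched lift-table file."""


def equilibrium_fraction(Re: float) -> float:
    """Equilibrium position fraction ``s_eq(Re)``.

    0.6 of the half-width in the low-Re limit, increasing toward the wall
    with Re and saturating at 0.75.
    """
    return 0.6 + 0.15 * (1.0 - math.exp(-Re / 250.0))


def fL_plane_poiseuille(s, Re: float):
    """Net inertial lift coefficient in plane Poiseuille flow.

    ``s`` is the lateral position as a fraction of the half-width in
    [-1, 1].  Odd in ``s``; positive (center-repelling) for
    ``0 < s < s_eq``, negative (wall-repelling) beyond.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(np.abs(s_arr) > 1 + 1e-12):
        raise ValueError("position fraction must lie in [-1, 1]")
    se = equilibrium_fraction(Re)
    out = LIFT_AMPLITUDE * s_arr * (se * se - s_arr * s_arr)
    return float(out) if np.isscalar(s) else out


def _lift_scale(spec: ChannelSpec, fluid: FluidProps, Q: float, a: float) -> float:
    U = characteristic_velocity(spec, Q)
    return fluid.density * U * U * a**4 / spec.hydraulic_diameter**2


class _AnalyticLift:
    """Shared plumbing for the closed-form providers."""

    provider = "analytic"

    def __init__(self, spec: ChannelSpec, fluid: FluidProps, Q: float, a: float):
        if not 0 < a < min(spec.width, spec.height) / 2:
            raise ValueError("particle radius incompatible with the cross-section")
        self.channel = spec
        self.fluid = fluid
        self.Q = Q
        self.particle_radius = a
        self.Re = channel_reynolds(spec, fluid, Q)
        self.scale = _lift_scale(spec, fluid, Q, a)

    def _fractions(self, x, z, clip: bool):
        sx = 2.0 * np.asarray(x, float) / self.channel.width
        sz = 2.0 * np.asarray(z, float) / self.channel.height
        if clip:
            sx = np.clip(sx, -1.0, 1.0)
            sz = np.clip(sz, -1.0, 1.0)
        else:
            amax = self.particle_radius
            if np.any(
                np.abs(np.asarray(x)) > self.channel.width / 2 - amax + 1e-15
            ) or np.any(np.abs(np.asarray(z)) > self.channel.height / 2 - amax + 1e-15):
                raise ValueError("particle center overlaps a wall")
        return sx, sz


class SuperposedLift(_AnalyticLift):
    """Plane-Poiseuille lift superposed per wall pair.

    ``F_xi = fL(2 xi/w, Re) * scale`` and ``F_zeta = fL(2 zeta/h, Re) *
    scale`` — each wall pair acts as an independent plane channel; the
    cross-coupling between the pairs is deliberately ignored.
    """

    provider = "asmolov_superposed"

    def force(self, x, z, clip: bool = True):
        sx, sz = self._fractions(x, z, clip)
        return (
            fL_plane_poiseuille(sx, self.Re) * self.scale,
            fL_plane_poiseuille(sz, self.Re) * self.scale,
        )


class HoodStyleLift(_AnalyticLift):
    """Synthetic lift field with axis-stable topology.

    Adds a quartic cross-coupling to the superposed cubic so that the stable
    zeros sit on the symmetry axes (and the diagonal zeros become saddles),
    the topology reported for the asymptotic 3D-Poiseuille solution:

        F_x ~ C sx (s_eq^2 - sx^2) - 2C sx sz^2
        F_z ~ C sz (s_eq^2 - sz^2) - 2C sz sx^2
    """

    provider = "hood_style"

    def force(self, x, z, clip: bool = True):
        sx, sz = self._fractions(x, z, clip)
        se2 = equilibrium_fraction(self.Re) ** 2
        C = LIFT_AMPLITUDE
        fx = C * sx * (se2 - sx * sx) - 2 * C * sx * sz * sz
        fz = C * sz * (se2 - sz * sz) - 2 * C * sz * sx * sx
        return fx * self.scale, fz * self.scale


class TabulatedLift:
    """Bilinear-interpolating lift field backed by a regular table."""

    provider = "table"

    def __init__(
        self,
        channel: ChannelSpec,
        xi: np.ndarray,
        zeta: np.ndarray,
        Fx: np.ndarray,
        Fz: np.ndarray,
        Re: float,
        particle_radius: float,
    ):
        self.channel = channel
        self.xi = np.asarray(xi, float)
        self.zeta = np.asarray(zeta, float)
        self.Fx = np.asarray(Fx, float)
        self.Fz = np.asarray(Fz, float)
        self.Re = Re
        self.particle_radius = particle_radius

    def force(self, x, z, clip: bool = True):
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        return (
            _bilinear(self.xi, self.zeta, self.Fx, x, z),
            _bilinear(self.xi, self.zeta, self.Fz, x, z),
        )


def save_lift_table(path, field, n_xi: int = 41, n_zeta: int = 41) -> None:
    """Export a lift field to the plain-text table format.

    Header lines carry the channel width/height, Re and particle radius in
    SI; data rows are ``xi zeta Fx Fz``.
    """
    ch = field.channel
    xi = np.linspace(-ch.width / 2, ch.width / 2, n_xi)
    zeta = np.linspace(-ch.height / 2, ch.height / 2, n_zeta)
    X, Z = np.meshgrid(xi, zeta, indexing="ij")
    Fx, Fz = field.force(X.ravel(), Z.ravel(), clip=True)
    with open(path, "w") as fh:
        fh.write(
            f"# w={float(ch.width)!r} h={float(ch.height)!r} Re={float(field.Re)!r} "
            f"a={float(field.particle_radius)!r}\n"
        )
        fh.write("# xi zeta Fx Fz (SI)\n")
        xr, zr = X.ravel(), Z.ravel()
        for k in range(X.size):
            fh.write(
                f"{float(xr[k])!r} {float(zr[k])!r} "
                f"{float(Fx[k])!r} {float(Fz[k])!r}\n"
            )


def load_lift_table(path, channel: ChannelSpec, tol: float = 0.01) -> TabulatedLift:
    """Read a lift table; header metadata must match ``channel`` within 1%."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        try:
                            header[key] = float(val)
                        except ValueError:
                            pass
                continue
            parts = line.split()
            if len(parts) != 4:
                raise LiftTableError(f"malformed row: {line!r}")
            rows.append([float(p) for p in parts])
    for key in ("w", "h", "Re", "a"):
        if key not in header:
            raise LiftTableError(f"missing header field {key!r}")
    if (
        abs(header["w"] - channel.width) > tol * channel.width
        or abs(header["h"] - channel.height) > tol * channel.height
    ):
        raise LiftTableError("table header does not match the active channel")
    data = np.asarray(rows)
    xi = np.unique(data[:, 0])
    zeta = np.unique(data[:, 1])
    if len(xi) * len(zeta) != len(data):
        raise LiftTableError("ragged grid: points do not form a regular lattice")
    order = np.lexsort((data[:, 1], data[:, 0]))
    data = data[order]
    Fx = data[:, 2].reshape(len(xi), len(zeta))
    Fz = data[:, 3].reshape(len(xi), len(zeta))
    return TabulatedLift(channel, xi, zeta, Fx, Fz, header["Re"], header["a"])


# ---------------------------------------------------------------------------
# equilibrium finding and classification


@dataclass(frozen=True)
class EquilibriumPoint:
    """A zero of the lateral lift field.

    ``kind`` is ``stable`` (both mobility-scaled Jacobian eigenvalues have
    negative real part), ``unstable`` (both positive) or ``saddle`` (mixed).
    Eigenvalues are in 1/s after scaling the force by the Stokes mobility.
    """

    xi: float
    zeta: float
    kind: str
    eigenvalues: tuple[complex, complex]


def _force_at(field, p):
    fx, fz = field.force(np.asarray([p[0]]), np.asarray([p[1]]), clip=True)
    return np.array([float(fx[0]), float(fz[0])])


def find_equilibria(
    field,
    mobility: float | None = None,
    n_grid: int = 81,
    margin: float | None = None,
) -> list[EquilibriumPoint]:
    """Locate and classify all interior zeros of a lift field.

    Sign-change bracketing on an ``n_grid``-squared scan of the admissible
    interior, followed by 2D root polishing and classification by the
    eigenvalues of the mobility-scaled force Jacobian (centered differences).
    """
    ch = field.channel
    if mobility is None:
        mu = getattr(field, "fluid", None)
        visc = mu.viscosity if mu is not None else 1e-3
        mobility = 1.0 / (6 * math.pi * visc * field.particle_radius)
    if margin is None:
        margin = max(field.particle_radius, 1e-3 * min(ch.width, ch.height))
    gx = np.linspace(-ch.width / 2 + margin, ch.width / 2 - margin, n_grid)
    gz = np.linspace(-ch.height / 2 + margin, ch.height / 2 - margin, n_grid)
    X, Z = np.meshgrid(gx, gz, indexing="ij")
    Fx, Fz = field.force(X.ravel(), Z.ravel(), clip=True)
    Fx = np.asarray(Fx).reshape(X.shape)
    Fz = np.asarray(Fz).reshape(X.shape)
    fmax = max(np.abs(Fx).max(), np.abs(Fz).max())
    if fmax == 0:
        return []

    def sign_change(F, i, j):
        cell = F[i : i + 2, j : j + 2]
        return cell.min() <= 0 <= cell.max()

    candidates = []
    for i in range(n_grid - 1):
        for j in range(n_grid - 1):
            if sign_change(Fx, i, j) and sign_change(Fz, i, j):
                candidates.append((0.5 * (gx[i] + gx[i + 1]), 0.5 * (gz[j] + gz[j + 1])))

    scale = np.array([ch.width, ch.height]) / 2

    def fun(q):
        return _force_at(field, q * scale) / fmax

    found: list[np.ndarray] = []
    for cand in candidates:
        q0 = np.asarray(cand) / scale
        sol = scipy.optimize.root(fun, q0, method="hybr")
        # accept by polished residual, not the solver status flag: hybr
        # reports "no progress" when the start is already near the root
        p = sol.x * scale
        if np.abs(p[0]) > ch.width / 2 - margin * 0.5 or np.abs(p[1]) > ch.height / 2 - margin * 0.5:
            continue
        if np.linalg.norm(_force_at(field, p)) > 1e-6 * fmax:
            continue
        if any(
            np.hypot(*(p - q) / scale) < 2.0 / n_grid for q in found
        ):
            continue
        found.append(p)

    points = []
    eps = 1e-4 * min(ch.width, ch.height)
    for p in found:
        J = np.zeros((2, 2))
        for k in range(2):
            dp = np.zeros(2)
            dp[k] = eps
            J[:, k] = (_force_at(field, p + dp) - _force_at(field, p - dp)) / (2 * eps)
        eig = np.linalg.eigvals(mobility * J)
        neg = np.real(eig) < 0
        if neg.all():
            kind = "stable"
        elif (~neg).all():
            kind = "unstable"
        else:
            kind = "saddle"
        points.append(
            EquilibriumPoint(
                xi=float(p[0]),
                zeta=float(p[1]),
                kind=kind,
                eigenvalues=(complex(eig[0]), complex(eig[1])),
            )
        )
    points.sort(key=lambda q: (round(q.xi, 12), round(q.zeta, 12)))
    return points
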