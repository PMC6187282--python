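"""Steady continuous-phase flow on the channel cross-section.

Two ingredients, computed on a regular ``(xi, zeta)`` grid:

* the fully developed axial duct profile ``u(xi, zeta)`` from the classical
  double-series solution for pressure-driven flow in a rectangular duct,
  rescaled so its quadrature-integrated flow rate equals ``Q`` exactly; and
* the first-order Dean secondary flow ``(v_xi, v_zeta)`` driven by the
  centrifugal imbalance ``rho u^2 / R``, obtained from a streamfunction-
  vorticity formulation with Thom-type wall closure.  The vorticity Poisson
  equation, the streamfunction Poisson equation and the Thom wall conditions
  are assembled into a single sparse linear system (nondimensionalized for
  conditioning) and solved directly.

Because the secondary problem is linear with forcing proportional to 1/R,
a :class:`FieldBank` stores solutions at a handful of radii spanning the
spiral and interpolates linearly in 1/R.

Velocity samples are mapped to cylindrical components by projecting the
axial component onto the local spiral tangent ``(R', R)/|(R', R)|`` with
``R' = pitch/(2 pi)``: the fluid follows the spiral, so it carries a small
radial drift ``~ u R'/R`` in addition to the Dean component.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ChannelSpec, FluidProps, GeometryError, OutOfChannelError

__all__ = [
    "CrossSectionField",
    "axial_profile",
    "dean_secondary",
    "sample_velocity",
    "FieldBank",
    "default_grid",
]


def default_grid(spec: ChannelSpec) -> tuple[int, int]:
    """Default grid resolution: finer across the longer dimension."""
    if spec.width >= 4 * spec.height:
        return 241, 41
    if spec.height >= 4 * spec.width:
        return 41, 241
    return 121, 61


@dataclass
class CrossSectionField:
    """Gridded velocity field on one cross-section.

    ``u`` is the axial component, ``v_xi``/``v_zeta`` the secondary (Dean)
    components, all shaped ``(n_xi, n_zeta)`` on the regular axes ``xi``,
    ``zeta``.  ``R`` is the centerline radius the secondary flow was computed
    for (``None`` for a straight duct).  ``psi`` is the secondary-flow
    streamfunction (``v_xi = dpsi/dzeta``, ``v_zeta = -dpsi/dxi``).
    """

    channel: ChannelSpec
    xi: np.ndarray
    zeta: np.ndarray
    u: np.ndarray
    v_xi: np.ndarray
    v_zeta: np.ndarray
    Q: float
    R: float | None = None
    psi: np.ndarray | None = None

    def _bilinear(self, F: np.ndarray, x, z):
        return _bilinear(self.xi, self.zeta, F, np.asarray(x, float), np.asarray(z, float))

    def sample_raw(self, x, z):
        """Bilinear sample of ``(v_xi, u, v_zeta)`` in the local frame."""
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        if np.any(np.abs(x) > self.xi[-1] * (1 + 1e-9) + 1e-18) or np.any(
            np.abs(z) > self.zeta[-1] * (1 + 1e-9) + 1e-18
        ):
            raise OutOfChannelError("sample point outside the cross-section")
        return (
            self._bilinear(self.v_xi, x, z),
            self._bilinear(self.u, x, z),
            self._bilinear(self.v_zeta, x, z),
        )

    def flow_rate(self) -> float:
        """Quadrature of the axial component over the cross-section."""
        return float(np.trapezoid(np.trapezoid(self.u, self.zeta, axis=1), self.xi))

    def lateral_flux(self, x: float) -> float:
        """Net lateral volume flux ``int v_xi dzeta`` at fixed ``xi``.

        Evaluated through the streamfunction: the integral of
        ``dpsi/dzeta`` across the section is ``psi(top) - psi(bottom)``,
        identically zero for closed Dean streamlines.
        """
        if self.psi is None:
            return 0.0
        top = float(self._bilinear(self.psi, np.asarray(x), self.zeta[-1]))
        bot = float(self._bilinear(self.psi, np.asarray(x), self.zeta[0]))
        return top - bot


def _bilinear(ax_x: np.ndarray, ax_z: np.ndarray, F: np.ndarray, x, z):
    """Vectorized bilinear interpolation; exact at the nodes."""
    dx = ax_x[1] - ax_x[0]
    dz = ax_z[1] - ax_z[0]
    fx = np.clip((x - ax_x[0]) / dx, 0.0, len(ax_x) - 1)
    fz = np.clip((z - ax_z[0]) / dz, 0.0, len(ax_z) - 1)
    # snap to the node when the division roundoff is the only offset
    nx = np.rint(fx)
    fx = np.where(np.abs(fx - nx) < 1e-9, nx, fx)
    nz = np.rint(fz)
    fz = np.where(np.abs(fz - nz) < 1e-9, nz, fz)
    i = np.minimum(fx.astype(np.int64), len(ax_x) - 2)
    j = np.minimum(fz.astype(np.int64), len(ax_z) - 2)
    tx = fx - i
    tz = fz - j
    return (
        F[i, j] * (1 - tx) * (1 - tz)
        + F[i + 1, j] * tx * (1 - tz)
        + F[i, j + 1] * (1 - tx) * tz
        + F[i + 1, j + 1] * tx * tz
    )


def axial_profile(
    spec: ChannelSpec,
    fluid: FluidProps,
    Q: float,
    n_xi: int | None = None,
    n_zeta: int | None = None,
    n_terms: int = 101,
) -> CrossSectionField:
    """Fully developed axial velocity in a rectangular duct.

    Evaluates the classical single-sum Fourier solution (cosine series across
    the height, hyperbolic closure across the width, expanded in whichever
    direction is shorter for fast convergence), then rescales so the
    trapezoid-quadrature flow rate equals ``Q`` exactly.
    """
    if n_xi is None or n_zeta is None:
        n_xi, n_zeta = default_grid(spec)
    if n_xi < 33 or n_zeta < 33:
        if min(n_xi, n_zeta) < 33:
            raise GeometryError("grid too coarse: need at least 33 nodes per side")
    if n_terms < 10:
        raise GeometryError("series truncation below 10 terms is refused")

    w, h = spec.width, spec.height
    xi = np.linspace(-w / 2, w / 2, n_xi)
    zeta = np.linspace(-h / 2, h / 2, n_zeta)
    # expand the cosine series across the shorter dimension
    if h <= w:
        X, Zc = np.meshgrid(xi, zeta, indexing="ij")
        half_long, half_short = w / 2, h / 2
    else:
        Zc, X = np.meshgrid(xi, zeta, indexing="ij")
        half_long, half_short = h / 2, w / 2
    u = np.zeros((n_xi, n_zeta))
    for n in range(1, 2 * n_terms, 2):
        k = n * math.pi / (2 * half_short)
        # cosh(k X)/cosh(k a) computed in exp form to avoid overflow
        ratio = (
            np.exp(k * (np.abs(X) - half_long))
            * (1 + np.exp(-2 * k * np.abs(X)))
            / (1 + math.exp(-2 * k * half_long))
        )
        u += (-1) ** ((n - 1) // 2) / n**3 * (1 - ratio) * np.cos(k * Zc)
    # clear series roundoff on the walls before normalizing: exact no-slip
    u[0, :] = u[-1, :] = 0.0
    u[:, 0] = u[:, -1] = 0.0
    integral = np.trapezoid(np.trapezoid(u, zeta, axis=1), xi)
    u *= Q / integral
    zeros = np.zeros_like(u)
    return CrossSectionField(
        channel=spec, xi=xi, zeta=zeta, u=u, v_xi=zeros, v_zeta=zeros.copy(), Q=Q
    )


def dean_secondary(
    spec: ChannelSpec,
    fluid: FluidProps,
    Q: float,
    R: float,
    axial: CrossSectionField,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order Dean secondary flow at centerline radius ``R``.

    Solves the Stokes balance with centrifugal forcing:
    ``lap(omega) = -(rho/(mu R)) d(u^2)/dzeta`` and ``lap(psi) = -omega``
    with ``psi = 0`` and Thom-closed wall vorticity on all four walls.
    Returns ``(v_xi, v_zeta, psi)``.  The sign convention is fixed so that
    ``v_xi > 0`` (toward the outer wall) on the mid-plane.
    """
    if R < 2 * spec.width:
        raise GeometryError("Dean perturbation requires R >= 2 w (small curvature)")
    xi, zeta, u = axial.xi, axial.zeta, axial.u
    nx, nz = u.shape
    dxp = xi[1] - xi[0]
    dzp = zeta[1] - zeta[0]

    b = spec.height / 2.0  # length scale for nondimensional assembly
    dx = dxp / b
    dz = dzp / b

    u2 = u * u
    du2dz = np.zeros_like(u)
    du2dz[:, 1:-1] = (u2[:, 2:] - u2[:, :-2]) / (2 * dzp)
    f = -(fluid.density / (fluid.viscosity * R)) * du2dz
    Fmax = np.abs(f).max()
    omega_scale = Fmax * b * b if Fmax > 0 else 1.0
    fh = f * b * b / omega_scale

    N = nx * nz
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(2 * N)

    def idx(i: int, j: int) -> int:
        return i * nz + j

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    cxx, czz = 1 / dx**2, 1 / dz**2
    diag = -2 * cxx - 2 * czz
    for i in range(nx):
        for j in range(nz):
            r = idx(i, j)
            rp = N + r
            interior = 0 < i < nx - 1 and 0 < j < nz - 1
            if interior:
                add(r, idx(i, j), diag)
                add(r, idx(i - 1, j), cxx)
                add(r, idx(i + 1, j), cxx)
                add(r, idx(i, j - 1), czz)
                add(r, idx(i, j + 1), czz)
                rhs[r] = fh[i, j]
                add(rp, N + idx(i, j), diag)
                add(rp, N + idx(i - 1, j), cxx)
                add(rp, N + idx(i + 1, j), cxx)
                add(rp, N + idx(i, j - 1), czz)
                add(rp, N + idx(i, j + 1), czz)
                add(rp, idx(i, j), 1.0)  # lap(psi) + omega = 0
            else:
                # Thom closure: omega_wall = -2 psi_adjacent / dn^2
                add(r, idx(i, j), 1.0)
                if i == 0 and 0 < j < nz - 1:
                    add(r, N + idx(1, j), 2 * cxx)
                elif i == nx - 1 and 0 < j < nz - 1:
                    add(r, N + idx(nx - 2, j), 2 * cxx)
                elif j == 0 and 0 < i < nx - 1:
                    add(r, N + idx(i, 1), 2 * czz)
                elif j == nz - 1 and 0 < i < nx - 1:
                    add(r, N + idx(i, nz - 2), 2 * czz)
                add(rp, N + idx(i, j), 1.0)  # psi = 0 on walls

    A = sp.csc_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(2 * N, 2 * N)
    )
    sol = spla.splu(A).solve(rhs)
    resid = np.abs(A @ sol - rhs).max()
    if not np.isfinite(resid) or resid > 1e-6 * max(1.0, np.abs(rhs).max()):
        raise RuntimeError(f"secondary-flow linear solve failed, residual {resid:.3e}")

    psi = sol[N:].reshape(nx, nz) * omega_scale * b * b
    # the continuous problem is exactly antisymmetric in zeta; enforce it
    psi = 0.5 * (psi - psi[:, ::-1])
    v_xi = np.zeros_like(psi)
    v_zeta = np.zeros_like(psi)
    v_xi[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2 * dzp)
    v_zeta[1:-1, :] = -(psi[2:, :] - psi[:-2, :]) / (2 * dxp)
    if v_xi[nx // 2, nz // 2] < 0:
        v_xi, v_zeta, psi = -v_xi, -v_zeta, -psi
    return v_xi, v_zeta, psi


def make_field(
    spec: ChannelSpec,
    fluid: FluidProps,
    Q: float,
    R: float | None,
    n_xi: int | None = None,
    n_zeta: int | None = None,
) -> CrossSectionField:
    """Axial plus (for finite ``R``) Dean secondary flow at one radius."""
    fld = axial_profile(spec, fluid, Q, n_xi, n_zeta)
    if R is not None and np.isfinite(R):
        v_xi, v_zeta, psi = dean_secondary(spec, fluid, Q, R, fld)
        fld.v_xi, fld.v_zeta, fld.psi, fld.R = v_xi, v_zeta, psi, R
    return fld


def sample_velocity(field: CrossSectionField, x, z):
    """Sample ``(uf_r, uf_theta, uf_z)`` at local position ``(xi, zeta)``.

    The axial component is projected onto the spiral tangent when the field
    carries a finite reference radius; for a straight duct (``R`` is None)
    the axial component maps to ``uf_theta`` directly.
    """
    v_xi, u, v_zeta = field.sample_raw(x, z)
    if field.R is None:
        return v_xi, u, v_zeta
    Rp = field.channel.pitch / (2 * math.pi)
    nrm = math.hypot(Rp, field.R)
    return v_xi + u * Rp / nrm, u * field.R / nrm, v_zeta


class FieldBank:
    """Frozen-coefficient flow fields across the spiral.

    The axial profile is computed once (radius-independent); the Dean
    secondary flow is computed at ``n_radii`` stations spanning the spiral
    and interpolated linearly in 1/R (the first-order Dean amplitude is
    proportional to 1/R).  ``straight=True`` produces a bank with no
    secondary flow and no spiral tangent projection, for straight-duct
    experiments.
    """

    def __init__(
        self,
        spec: ChannelSpec,
        fluid: FluidProps,
        Q: float,
        n_radii: int = 8,
        n_xi: int | None = None,
        n_zeta: int | None = None,
        straight: bool = False,
    ):
        if n_radii < 2 and not straight:
            raise GeometryError("need at least two radii for the field bank")
        self.channel = spec
        self.fluid = fluid
        self.Q = Q
        self.straight = straight
        self.axial = axial_profile(spec, fluid, Q, n_xi, n_zeta)
        self.xi = self.axial.xi
        self.zeta = self.axial.zeta
        self._warned_clamp = False
        if straight:
            self.radii = np.array([])
            self.inv_radii = np.array([])
            self._VX = self._VZ = self._PSI = None
            return
        R_in = spec.r0
        R_out = spec.r0 + spec.pitch * spec.n_turns
        radii = 1.0 / np.linspace(1.0 / R_in, 1.0 / R_out, n_radii)
        vx_list, vz_list, psi_list = [], [], []
        for R in radii:
            v_xi, v_zeta, psi = dean_secondary(spec, fluid, Q, R, self.axial)
            vx_list.append(v_xi)
            vz_list.append(v_zeta)
            psi_list.append(psi)
        order = np.argsort(1.0 / radii)
        self.radii = radii[order]
        self.inv_radii = 1.0 / self.radii
        self._VX = np.stack([vx_list[k] for k in order])
        self._VZ = np.stack([vz_list[k] for k in order])
        self._PSI = np.stack([psi_list[k] for k in order])

    # -- queries ---------------------------------------------------------

    def _clamp_inv(self, invR: np.ndarray) -> np.ndarray:
        lo, hi = self.inv_radii[0], self.inv_radii[-1]
        # a predictor step may poke marginally past the outlet; stay quiet there
        if np.any(invR < lo * (1 - 1e-3)) or np.any(invR > hi * (1 + 1e-3)):
            if not self._warned_clamp:
                warnings.warn(
                    "field-bank query outside sampled radii; clamping",
                    stacklevel=3,
                )
                self._warned_clamp = True
        return np.clip(invR, lo, hi)

    def _secondary_at(self, x, z, R):
        """Per-point bilinear sample of the secondary field, 1/R interpolated."""
        invR = self._clamp_inv(1.0 / np.asarray(R, float))
        k = np.clip(
            np.searchsorted(self.inv_radii, invR) - 1, 0, len(self.inv_radii) - 2
        )
        wgt = (invR - self.inv_radii[k]) / (self.inv_radii[k + 1] - self.inv_radii[k])
        ax, az = self.xi, self.zeta
        dx = ax[1] - ax[0]
        dz = az[1] - az[0]
        fx = np.clip((x - ax[0]) / dx, 0.0, len(ax) - 1 - 1e-12)
        fz = np.clip((z - az[0]) / dz, 0.0, len(az) - 1 - 1e-12)
        i = fx.astype(np.int64)
        j = fz.astype(np.int64)
        tx = fx - i
        tz = fz - j

        def lvl(A, kk):
            return (
                A[kk, i, j] * (1 - tx) * (1 - tz)
                + A[kk, i + 1, j] * tx * (1 - tz)
                + A[kk, i, j + 1] * (1 - tx) * tz
                + A[kk, i + 1, j + 1] * tx * tz
            )

        v_xi = (1 - wgt) * lvl(self._VX, k) + wgt * lvl(self._VX, k + 1)
        v_zeta = (1 - wgt) * lvl(self._VZ, k) + wgt * lvl(self._VZ, k + 1)
        return v_xi, v_zeta

    def sample(self, x, z, R):
        """Cylindrical velocity components ``(uf_r, uf_theta, uf_z)``.

        ``x``/``z`` are local cross-section coordinates and ``R`` the local
        centerline radius; all may be arrays of matching shape.
        """
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        u = _bilinear(self.xi, self.zeta, self.axial.u, x, z)
        if self.straight:
            zero = np.zeros_like(u)
            return zero, u, zero.copy()
        v_xi, v_zeta = self._secondary_at(x, z, np.asarray(R, float))
        Rp = self.channel.pitch / (2 * math.pi)
        R = np.asarray(R, float)
        nrm = np.sqrt(Rp * Rp + R * R)
        return v_xi + u * Rp / nrm, u * R / nrm, v_zeta

    def field_at(self, R: float) -> CrossSectionField:
        """Cross-section field at radius ``R`` (1/R interpolation of the bank)."""
        if self.straight:
            fld = self.axial
            return CrossSectionField(
                channel=self.channel,
                xi=self.xi,
                zeta=self.zeta,
                u=fld.u,
                v_xi=np.zeros_like(fld.u),
                v_zeta=np.zeros_like(fld.u),
                Q=self.Q,
            )
        invR = float(self._clamp_inv(np.asarray(1.0 / R)))
        k = int(np.clip(np.searchsorted(self.inv_radii, invR) - 1, 0, len(self.inv_radii) - 2))
        wgt = (invR - self.inv_radii[k]) / (self.inv_radii[k + 1] - self.inv_radii[k])
        v_xi = (1 - wgt) * self._VX[k] + wgt * self._VX[k + 1]
        v_zeta = (1 - wgt) * self._VZ[k] + wgt * self._VZ[k + 1]
        psi = (1 - wgt) * self._PSI[k] + wgt * self._PSI[k + 1]
        return CrossSectionField(
            channel=self.channel,
            xi=self.xi,
            zeta=self.zeta,
            u=self.axial.u,
            v_xi=v_xi,
            v_zeta=v_zeta,
            Q=self.Q,
            R=R,
            psi=psi,
        )
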