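"""Single-particle dynamics: forces and the implicit predictor-corrector.

The particle momentum balance (neutrally buoyant, buoyancy dropped, virtual
mass folded into the effective inertia) in cylindrical coordinates is

    dup/dt = G = (2/(3 Mp)) (FD + FL + (Mp/2) duf/dt)
                 + (up_th^2/r, -up_r up_th/r, 0)

with Stokes drag ``FD = 6 pi mu Rp (uf - up)``, the lateral inertial lift
``FL`` and the fluid acceleration ``duf/dt`` discretized by a backward
difference along the trajectory.  The drag part reduces to ``(uf - up)/tau``
with the virtual-mass-modified relaxation time ``tau = rho_f Rp^2/(3 mu)``.

Time stepping is the implicit trapezoidal rule for the velocity,

    up^{k+1} = up^k + (dt/2) (G^k + G^{k+1}),

with an explicit-Euler position predictor, a damped Newton solve of the
three-component nonlinear system for ``up^{k+1}`` (analytic Jacobian), and a
trapezoidal position corrector.  Wall handling projects the particle center
back to the admissible region and zeroes the wall-normal velocity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .flowfield import FieldBank
from .geometry import ChannelSpec, FluidProps, GeometryError, ParticleSpec

__all__ = [
    "ParticleState",
    "StepConfig",
    "StepFailure",
    "drag_force",
    "relaxation_time",
    "rhs_G",
    "predict_position",
    "solve_velocity_implicit",
    "correct_position",
    "step",
]


class StepFailure(RuntimeError):
    """The implicit velocity solve failed to converge."""


@dataclass
class ParticleState:
    """Position, velocity and cached fluid velocity of one particle.

    Positions are cylindrical ``(r, theta, z)`` and velocities their
    components ``(up_r, up_theta, up_z)``.  ``uf_prev`` is the fluid
    velocity sampled at the previous step, needed for the backward
    difference of the fluid acceleration.
    """

    t: float
    r: float
    theta: float
    z: float
    v: np.ndarray  # (up_r, up_theta, up_z)
    uf_prev: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.uf_prev = np.asarray(self.uf_prev, dtype=float)
        if not (
            np.isfinite(self.v).all()
            and np.isfinite(self.uf_prev).all()
            and np.isfinite([self.t, self.r, self.theta, self.z]).all()
        ):
            raise ValueError("non-finite particle state")


@dataclass(frozen=True)
class StepConfig:
    """Integrator controls.

    ``dt`` in s; ``tol`` is the Newton update norm tolerance in m/s;
    ``max_halvings`` bounds the dt-halving retries on a failed solve.
    """

    dt: float
    tol: float = 1e-12
    max_iter: int = 30
    damping: float = 1.0
    max_halvings: int = 5
    project_walls: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tol <= 0:
            raise ValueError("dt and tolerance must be positive")


def relaxation_time(fluid: FluidProps, particle: ParticleSpec) -> float:
    """Drag relaxation time ``tau = rho_f Rp^2 / (3 mu)`` (virtual mass
    included, neutrally buoyant)."""
    return fluid.density * particle.radius**2 / (3.0 * fluid.viscosity)


def drag_force(fluid: FluidProps, Rp: float, uf: np.ndarray, up: np.ndarray) -> np.ndarray:
    """Stokes drag ``6 pi mu Rp (uf - up)``, componentwise."""
    return 6.0 * math.pi * fluid.viscosity * Rp * (np.asarray(uf) - np.asarray(up))


def rhs_G(
    r: float,
    v: np.ndarray,
    uf: np.ndarray,
    duf_dt: np.ndarray,
    FL: np.ndarray,
    fluid: FluidProps,
    particle: ParticleSpec,
) -> np.ndarray:
    """Acceleration-like right-hand side ``G`` at one state.

    ``duf_dt`` is the finite-difference fluid acceleration for this step
    (backward form at step k, forward form at step k+1).
    """
    if r <= 0:
        raise GeometryError("radius must be positive")
    Mp = particle.mass
    v = np.asarray(v, float)
    uf = np.asarray(uf, float)
    FD = drag_force(fluid, particle.radius, uf, v)
    fict = np.array([v[1] ** 2 / r, -v[0] * v[1] / r, 0.0])
    return 2.0 / (3.0 * Mp) * (FD + np.asarray(FL) + 0.5 * Mp * np.asarray(duf_dt)) + fict


def predict_position(state: ParticleState, dt: float) -> tuple[float, float, float]:
    """Explicit-Euler position predictor ``x + (r', th', z') dt`` with
    ``(r', th', z') = (up_r, up_th/r, up_z)``."""
    return (
        state.r + state.v[0] * dt,
        state.theta + state.v[1] / state.r * dt,
        state.z + state.v[2] * dt,
    )


def correct_position(
    state: ParticleState, v_new: np.ndarray, dt: float
) -> tuple[float, float, float]:
    """Trapezoidal position corrector; the angular rate at k+1 uses the
    updated radius."""
    r_new = state.r + 0.5 * dt * (state.v[0] + v_new[0])
    z_new = state.z + 0.5 * dt * (state.v[2] + v_new[2])
    th_new = state.theta + 0.5 * dt * (state.v[1] / state.r + v_new[1] / r_new)
    return r_new, th_new, z_new


def _drag_rate(fluid: FluidProps, particle: ParticleSpec) -> float:
    # (2/(3 Mp)) * 6 pi mu Rp == 1/tau
    return 1.0 / relaxation_time(fluid, particle)


def solve_velocity_implicit(
    v_k: np.ndarray,
    G_k: np.ndarray,
    uf_k1: np.ndarray,
    duf_dt_k1: np.ndarray,
    FL_k1: np.ndarray,
    r_k1: float,
    fluid: FluidProps,
    particle: ParticleSpec,
    cfg: StepConfig,
    dt: float | None = None,
) -> np.ndarray:
    """Damped Newton solve of the trapezoidal velocity update.

    Solves ``v - v_k - (dt/2)(G_k + G(v))`` for the velocity at step k+1,
    with the step-k velocity as the initial guess.  The Jacobian of ``G``
    with respect to ``v`` is analytic: ``-I/tau`` from drag plus the
    centrifugal-coupling block.
    """
    dt = cfg.dt if dt is None else dt
    Mp = particle.mass
    inv_tau = _drag_rate(fluid, particle)
    const = np.asarray(v_k, float) + 0.5 * dt * np.asarray(G_k, float)
    lift_term = 2.0 / (3.0 * Mp) * np.asarray(FL_k1, float) + np.asarray(duf_dt_k1) / 3.0

    def G_of(v):
        fict = np.array([v[1] ** 2 / r_k1, -v[0] * v[1] / r_k1, 0.0])
        return (uf_k1 - v) * inv_tau + lift_term + fict

    v = np.asarray(v_k, float).copy()
    phi = v - const - 0.5 * dt * G_of(v)
    res = np.linalg.norm(phi)
    for _ in range(cfg.max_iter):
        if res < cfg.tol:
            return v
        J = np.eye(3) * (1.0 + 0.5 * dt * inv_tau)
        J[0, 1] -= 0.5 * dt * 2.0 * v[1] / r_k1
        J[1, 0] += 0.5 * dt * v[1] / r_k1
        J[1, 1] += 0.5 * dt * v[0] / r_k1
        dv = np.linalg.solve(J, phi)
        lam = cfg.damping
        for _ in range(6):
            v_trial = v - lam * dv
            phi_trial = v_trial - const - 0.5 * dt * G_of(v_trial)
            res_trial = np.linalg.norm(phi_trial)
            if res_trial <= res or res < cfg.tol:
                break
            lam *= 0.5
        if np.linalg.norm(lam * dv) < cfg.tol:
            return v_trial
        v, phi, res = v_trial, phi_trial, res_trial
    if res < math.sqrt(cfg.tol):
        return v
    raise StepFailure(f"velocity solve stalled at residual {res:.3e}")


def step(
    state: ParticleState,
    bank: FieldBank,
    lift_field,
    particle: ParticleSpec,
    cfg: StepConfig,
) -> ParticleState:
    """Advance one particle by one step (predict, solve, correct, project).

    Retries with a halved dt (up to ``cfg.max_halvings`` times) if the
    implicit solve fails; the successful sub-dt is used for the whole step
    in that case.
    """
    ch = bank.channel
    fluid = bank.fluid
    lim_x = ch.width / 2 - particle.radius
    lim_z = ch.height / 2 - particle.radius
    pitch_rate = ch.pitch / (2 * math.pi)

    def local(r, th, z):
        R = ch.r0 + pitch_rate * th
        return r - R, z, R

    dt = cfg.dt
    for attempt in range(cfg.max_halvings + 1):
        try:
            x_k, z_k, R_k = local(state.r, state.theta, state.z)
            ufr, ufth, ufz = bank.sample(np.asarray(x_k), np.asarray(z_k), np.asarray(R_k))
            uf_k = np.array([float(ufr), float(ufth), float(ufz)])
            FLx, FLz = lift_field.force(np.asarray([x_k]), np.asarray([z_k]), clip=True)
            FL_k = np.array([float(np.asarray(FLx).ravel()[0]), 0.0, float(np.asarray(FLz).ravel()[0])])
            duf_dt_k = (uf_k - state.uf_prev) / dt
            G_k = rhs_G(state.r, state.v, uf_k, duf_dt_k, FL_k, fluid, particle)

            r_p, th_p, z_p = predict_position(state, dt)
            x_p, z_pc, R_p = local(r_p, th_p, z_p)
            x_p = float(np.clip(x_p, -lim_x, lim_x))
            z_pc = float(np.clip(z_pc, -lim_z, lim_z))
            ufr, ufth, ufz = bank.sample(np.asarray(x_p), np.asarray(z_pc), np.asarray(R_p))
            uf_k1 = np.array([float(ufr), float(ufth), float(ufz)])
            FLx, FLz = lift_field.force(np.asarray([x_p]), np.asarray([z_pc]), clip=True)
            FL_k1 = np.array([float(np.asarray(FLx).ravel()[0]), 0.0, float(np.asarray(FLz).ravel()[0])])
            duf_dt_k1 = (uf_k1 - uf_k) / dt

            v_new = solve_velocity_implicit(
                state.v, G_k, uf_k1, duf_dt_k1, FL_k1, r_p, fluid, particle, cfg, dt=dt
            )
            break
        except StepFailure:
            if attempt == cfg.max_halvings:
                raise
            dt *= 0.5

    r_n, th_n, z_n = correct_position(state, v_new, dt)
    v_out = v_new.copy()
    if cfg.project_walls:
        R_n = ch.r0 + pitch_rate * th_n
        x_n = r_n - R_n
        if abs(x_n) > lim_x:
            x_n = float(np.clip(x_n, -lim_x, lim_x))
            r_n = R_n + x_n
            v_out[0] = 0.0
        if abs(z_n) > lim_z:
            z_n = float(np.clip(z_n, -lim_z, lim_z))
            v_out[2] = 0.0
    return ParticleState(
        t=state.t + dt, r=r_n, theta=th_n, z=z_n, v=v_out, uf_prev=uf_k
    )
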