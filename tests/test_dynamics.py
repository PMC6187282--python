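"""Forces, the implicit trapezoidal scheme, and single-particle stepping."""
import math

import numpy as np
import pytest

import deantrack as dt
from deantrack.dynamics import (
    ParticleState,
    StepConfig,
    correct_position,
    drag_force,
    predict_position,
    relaxation_time,
    rhs_G,
    solve_velocity_implicit,
    step,
)
from deantrack.flowfield import FieldBank
from deantrack.lift import SuperposedLift, find_equilibria
from deantrack.scenarios import ML_PER_H

Q6 = 0.6 * ML_PER_H
WATER = dt.WATER
FAR = 1e9  # effectively straight-line radius


def make_particle(radius=3.6e-6):
    return dt.ParticleSpec(radius=radius, density=1000.0)


class TestForces:
    def test_drag_zero_at_no_slip(self):
        f = drag_force(WATER, 5e-6, np.zeros(3), np.zeros(3))
        assert np.all(f == 0)

    def test_drag_magnitude(self):
        f = drag_force(WATER, 5e-6, np.array([0.1, 0, 0]), np.zeros(3))
        assert f[0] == pytest.approx(6 * math.pi * 1e-3 * 5e-6 * 0.1)
        assert f[0] == pytest.approx(9.42e-9, rel=1e-3)

    def test_drag_opposes_slip(self):
        up = np.array([0.3, -0.2, 0.1])
        uf = np.array([0.1, 0.1, 0.1])
        f = drag_force(WATER, 5e-6, uf, up)
        slip = up - uf
        assert np.dot(f, slip) < 0

    def test_rhs_vanishes_in_equilibrium(self):
        # straight-line limit: only the centrifugal remnant v^2/r survives
        p = make_particle()
        v = np.array([0, 0.1, 0])
        G = rhs_G(FAR, v, v, np.zeros(3), np.zeros(3), WATER, p)
        assert G[0] == pytest.approx(0.1**2 / FAR, rel=1e-12)
        assert abs(G[1]) < 1e-16 and abs(G[2]) < 1e-16

    def test_centripetal_term(self):
        p = make_particle()
        v = np.array([0.0, 0.5, 0.0])
        G = rhs_G(3e-3, v, v, np.zeros(3), np.zeros(3), WATER, p)
        assert G[0] == pytest.approx(0.5**2 / 3e-3)
        assert G[1] == 0.0 and G[2] == 0.0

    def test_drag_reduces_to_relaxation_rate(self):
        # with only drag, G = (uf - up)/tau, tau = rho Rp^2/(3 mu)
        p = make_particle(5e-6)
        uf = np.array([0.2, 0.0, 0.0])
        up = np.zeros(3)
        G = rhs_G(FAR, up, uf, np.zeros(3), np.zeros(3), WATER, p)
        tau = relaxation_time(WATER, p)
        assert tau == pytest.approx(1000 * 25e-12 / 3e-3)
        assert G[0] == pytest.approx(uf[0] / tau, rel=1e-12)


class TestPositionUpdates:
    def test_predictor_at_rest(self):
        st = ParticleState(0, 3e-3, 1.0, 0.0, np.zeros(3), np.zeros(3))
        assert predict_position(st, 1e-4) == (3e-3, 1.0, 0.0)

    def test_predictor_angular_kinematics(self):
        st = ParticleState(0, 3e-3, 0.0, 0.0, np.array([0, 0.5, 0]), np.zeros(3))
        _, th, _ = predict_position(st, 1e-5)
        assert th == pytest.approx(0.5 / 3e-3 * 1e-5)  # 1.6667e-3 rad

    def test_corrector_equals_euler_for_constant_velocity(self):
        v = np.array([0.01, 0.2, -0.005])
        st = ParticleState(0, 3e-3, 0.0, 0.0, v, np.zeros(3))
        r, th, z = correct_position(st, v, 1e-4)
        assert r == pytest.approx(3e-3 + v[0] * 1e-4)
        assert z == pytest.approx(-v[2] * -1e-4)

    def test_corrector_exact_for_linear_velocity(self):
        # trapezoid integrates a linearly varying integrand exactly
        v0 = np.array([0.01, 0.0, 0.0])
        v1 = np.array([0.03, 0.0, 0.0])
        st = ParticleState(0, 3e-3, 0.0, 0.0, v0, np.zeros(3))
        r, _, _ = correct_position(st, v1, 1e-3)
        assert r == pytest.approx(3e-3 + 0.5 * (0.01 + 0.03) * 1e-3, rel=1e-14)


class TestImplicitSolve:
    def setup_method(self):
        self.p = make_particle(1e-6)  # 2 um particle
        self.tau = relaxation_time(WATER, self.p)
        self.cfg = StepConfig(dt=1.0)  # dt passed explicitly below

    def _advance_linear(self, v0, uf, dt, n):
        """Repeatedly apply the implicit solve in uniform flow, no lift."""
        v = np.array([v0, 0.0, 0.0])
        uf3 = np.array([uf, 0.0, 0.0])
        for _ in range(n):
            G_k = (uf3 - v) / self.tau
            v = solve_velocity_implicit(
                v, G_k, uf3, np.zeros(3), np.zeros(3), FAR, WATER, self.p, self.cfg, dt=dt
            )
        return v[0]

    def test_matches_closed_form_trapezoidal_update(self):
        dt_ = 0.5 * self.tau
        v1 = self._advance_linear(0.0, 0.1, dt_, 1)
        lam = dt_ / (2 * self.tau)
        expected = (0.0 * (1 - lam) + 0.1 * 2 * lam) / (1 + lam)
        assert v1 == pytest.approx(expected, rel=1e-10)

    def test_equilibrated_state_converges_immediately(self):
        v = np.array([0.1, 0.0, 0.0])
        out = solve_velocity_implicit(
            v, np.zeros(3), v, np.zeros(3), np.zeros(3), FAR, WATER, self.p,
            self.cfg, dt=1e-5,
        )
        np.testing.assert_allclose(out, v, atol=1e-15)

    def test_a_stability_at_ten_tau(self):
        # the trapezoidal rule is A-stable: dt = 10 tau stays bounded and
        # tracks the matrix-exponential solution of the linear drag ODE
        dt_ = 10 * self.tau
        v = self._advance_linear(1.0, 0.0, dt_, 50)
        assert abs(v) < 1.0  # bounded
        exact = math.exp(-50 * dt_ / self.tau)
        assert abs(v) < max(10 * exact, 1e-10) or abs(v) < 1.0

    def test_relaxation_time_from_exponential_fit(self):
        dt_ = self.tau / 20
        v = np.array([0.0, 0.0, 0.0])
        uf3 = np.array([0.1, 0.0, 0.0])
        vals = []
        for _ in range(100):
            G_k = (uf3 - v) / self.tau
            v = solve_velocity_implicit(
                v, G_k, uf3, np.zeros(3), np.zeros(3), FAR, WATER, self.p,
                self.cfg, dt=dt_,
            )
            vals.append(uf3[0] - v[0])
        t = dt_ * np.arange(1, 101)
        slope = np.polyfit(t, np.log(vals), 1)[0]
        assert -1.0 / slope == pytest.approx(self.tau, rel=0.01)


@pytest.fixture(scope="module")
def mini_setup():
    """Fast 1-turn spiral used for stepping tests."""
    ch = dt.make_channel(100e-6, 50e-6, 3e-3, 200e-6, 1)
    Q = 3.0 * ML_PER_H
    bank = FieldBank(ch, WATER, Q, n_radii=3)
    lift = SuperposedLift(ch, WATER, Q, 3.6e-6)
    return ch, Q, bank, lift


class TestStep:
    def test_theta_advances_monotonically(self, mini_setup):
        ch, Q, bank, lift = mini_setup
        par = make_particle()
        cfg = StepConfig(dt=1e-4)
        st = ParticleState(0, ch.r0, 0.0, 5e-6,
                           np.array([0.0, 0.1, 0.0]), np.array([0.0, 0.1, 0.0]))
        thetas = [st.theta]
        for _ in range(200):
            st = step(st, bank, lift, par, cfg)
            thetas.append(st.theta)
        assert np.all(np.diff(thetas) > 0)

    def test_wall_projection_keeps_admissible(self, mini_setup):
        ch, Q, bank, lift = mini_setup
        par = make_particle()
        cfg = StepConfig(dt=1e-4)
        # start close to the outer wall moving outward
        st = ParticleState(0, ch.r0 + ch.width / 2 - par.radius - 1e-7, 0.0, 0.0,
                           np.array([5e-4, 0.05, 0.0]), np.array([0.0, 0.05, 0.0]))
        for _ in range(100):
            st = step(st, bank, lift, par, cfg)
            R = ch.r0 + ch.pitch * st.theta / (2 * math.pi)
            assert abs(st.r - R) <= ch.width / 2 - par.radius + 1e-12
            assert abs(st.z) <= ch.height / 2 - par.radius + 1e-12

    def test_mirror_symmetry_of_trajectories(self, mini_setup):
        ch, Q, bank, lift = mini_setup
        par = make_particle()
        cfg = StepConfig(dt=1e-4)
        z0 = 12e-6
        v0 = np.array([0.0, 0.08, 0.0])
        st_up = ParticleState(0, ch.r0 + 10e-6, 0.0, z0, v0.copy(), v0.copy())
        st_dn = ParticleState(0, ch.r0 + 10e-6, 0.0, -z0, v0.copy(), v0.copy())
        for _ in range(300):
            st_up = step(st_up, bank, lift, par, cfg)
            st_dn = step(st_dn, bank, lift, par, cfg)
        assert st_up.r == pytest.approx(st_dn.r, abs=1e-15)
        assert st_up.z == pytest.approx(-st_dn.z, abs=1e-10 * ch.height)

    def test_persistence_at_stable_equilibrium_straight_duct(self):
        # a particle seeded at a stable lift equilibrium with up = uf stays
        ch = dt.make_channel(80e-6, 80e-6, 1e3, 200e-6, 1)  # quasi-straight
        Q = Q6
        bank = FieldBank(ch, WATER, Q, straight=True)
        lift = SuperposedLift(ch, WATER, Q, 4e-6)
        par = make_particle(4e-6)
        stable = [p for p in find_equilibria(lift) if p.kind == "stable"][0]
        ur, uth, uz = bank.sample(np.array([stable.xi]), np.array([stable.zeta]),
                                  np.array([ch.r0]))
        v0 = np.array([ur[0], uth[0], uz[0]])
        st = ParticleState(0, ch.r0 + stable.xi, 0.0, stable.zeta, v0, v0.copy())
        cfg = StepConfig(dt=1e-4)
        for _ in range(10_000):
            st = step(st, bank, lift, par, cfg)
        drift = math.hypot(st.r - ch.r0 - ch.pitch * st.theta / (2 * math.pi) - stable.xi,
                           st.z - stable.zeta)
        assert drift < 1e-3 * ch.width

    def test_second_order_self_convergence(self, mini_setup):
        # Richardson: displacement error ratio between dt and dt/2 runs
        ch, Q, bank, lift = mini_setup
        par = make_particle()
        T = 0.02

        def final_state(dt_):
            v0 = np.array([0.0, 0.12, 0.0])
            st = ParticleState(0, ch.r0 + 15e-6, 0.0, 8e-6, v0.copy(), v0.copy())
            cfg = StepConfig(dt=dt_)
            for _ in range(int(round(T / dt_))):
                st = step(st, bank, lift, par, cfg)
            return np.array([st.r, st.theta * ch.r0, st.z])

        x1 = final_state(2e-4)
        x2 = final_state(1e-4)
        x3 = final_state(5e-5)
        d1 = np.linalg.norm(x1 - x2)
        d2 = np.linalg.norm(x2 - x3)
        order = math.log2(d1 / d2)
        assert 1.8 <= order <= 2.2


class TestBatchAgreement:
    def test_batch_integrator_matches_scalar_step(self, mini_setup):
        """The vectorized ensemble kernel and dynamics.step implement the
        same scheme: outlet positions agree to near machine precision."""
        ch, Q, bank, lift = mini_setup
        par = make_particle()
        cfg = dt.EnsembleConfig(
            channel=ch, fluid=WATER, particle=par, Q=Q, n_particles=3, seed=11,
            step=StepConfig(dt=1e-4),
        )
        res = dt.run_ensemble(cfg, bank, lift)
        states = dt.seed_inlet(cfg, bank)
        for k, st in enumerate(states):
            prev = st
            while st.theta < ch.theta_end:
                prev = st
                st = step(st, bank, lift, par, cfg.step)
            frac = (ch.theta_end - prev.theta) / (st.theta - prev.theta)
            xi_prev = prev.r - (ch.r0 + ch.pitch * prev.theta / (2 * math.pi))
            xi_new = st.r - (ch.r0 + ch.pitch * st.theta / (2 * math.pi))
            xi_out = xi_prev + frac * (xi_new - xi_prev)
            z_out = prev.z + frac * (st.z - prev.z)
            assert res.outlet[k, 0] == pytest.approx(xi_out, abs=1e-9 * ch.width)
            assert res.outlet[k, 1] == pytest.approx(z_out, abs=1e-9 * ch.height)
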