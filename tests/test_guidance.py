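"""Guidance laws and the speed-matched forward-Euler simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import straight_target
from pursuitfit.geometry import GeometryError, signed_deviation_angle
from pursuitfit.guidance import (
    GuidanceLaw,
    GuidanceParams,
    InputCoverageError,
    SimConfig,
    commanded_acceleration,
    simulate_pursuit,
)

finite = st.floats(-10, 10, allow_nan=False)


def run_sim(times, tpos, tvel, speed, params, dt, r0, v0, t_end=None):
    cfg = SimConfig(dt=dt, tau_max=0.15, t_start=0.0)
    return simulate_pursuit(
        times,
        tpos,
        tvel,
        speed,
        np.empty((0, 2)),
        np.empty((0, 2)),
        params,
        cfg,
        init=(np.asarray(r0, float), np.asarray(v0, float)),
        t_end=t_end,
    )


def track_deviation(traj, tpos):
    los = tpos[: len(traj)] - traj.positions
    return signed_deviation_angle(los, traj.velocities)


class TestCommandedAcceleration:
    def test_pn_turn_rate_scales_velocity_rotation(self):
        p = GuidanceParams(GuidanceLaw.INERTIAL_PN, N=1.0)
        a = commanded_acceleration(p, 0.5, 0.3, np.array([10.0, 0.0]))
        assert a == pytest.approx([0.0, 5.0])  # K (and delta) ignored for PN

    def test_pp_zero_deviation_commands_nothing(self):
        p = GuidanceParams(GuidanceLaw.PP, K=5.0, N=2.0)
        a = commanded_acceleration(p, 0.7, 0.0, np.array([3.0, -4.0]))
        assert a == pytest.approx([0.0, 0.0])  # N (and los rate) ignored for PP

    def test_mixed_law_combines_both_terms(self):
        p = GuidanceParams(GuidanceLaw.INERTIAL_PNP, N=0.8, K=2.4)
        a = commanded_acceleration(p, 1.0, 0.1, np.array([8.0, 0.0]))
        assert a == pytest.approx([0.0, 4.48])

    def test_zero_velocity_raises(self):
        p = GuidanceParams(GuidanceLaw.PP, K=1.0)
        with pytest.raises(GeometryError):
            commanded_acceleration(p, 0.0, 0.1, np.zeros(2))

    @given(
        los=finite,
        delta=st.floats(-3, 3),
        vx=finite,
        vy=finite,
        n=st.floats(0, 2),
        k=st.floats(0, 5),
    )
    def test_acceleration_perpendicular_to_velocity(self, los, delta, vx, vy, n, k):
        if abs(vx) + abs(vy) < 1e-6:
            return
        p = GuidanceParams(GuidanceLaw.BACKGROUND_PNP, N=n, K=k)
        v = np.array([vx, vy])
        a = commanded_acceleration(p, los, delta, v)
        # the command only ever turns the velocity, never stretches it
        bound = 1e-12 * max(1.0, np.linalg.norm(a) * np.linalg.norm(v))
        assert abs(a @ v) <= bound


class TestSimulator:
    dt = 1e-3

    def test_pn_unit_gain_holds_aim_on_stationary_target(self):
        """With N = 1 the commanded turn rate equals the line-of-sight rate,
        so a pursuer launched straight at a stationary target stays aimed."""
        times, tpos, tvel = straight_target(self.dt, 2.0)
        speed = np.full(len(times), 6.0)
        r0 = np.array([0.0, 0.0])
        aim = (tpos[0] - r0) / np.linalg.norm(tpos[0] - r0)
        traj = run_sim(
            times, tpos, tvel, speed,
            GuidanceParams(GuidanceLaw.INERTIAL_PN, N=1.0, tau=0.0),
            self.dt, r0, 6.0 * aim, t_end=1.2,
        )
        assert np.max(np.abs(track_deviation(traj, tpos))) < 1e-9

    def test_background_pn_blind_to_own_heading_error(self):
        """A stationary target produces zero background LOS rate, so
        background-PN never steers: the flight is a straight line that does
        not converge on the line of sight."""
        times, tpos, tvel = straight_target(self.dt, 2.0)
        speed = np.full(len(times), 6.0)
        r0 = np.array([0.0, 0.0])
        aim = (tpos[0] - r0) / np.linalg.norm(tpos[0] - r0)
        rot = np.deg2rad(30)
        c, s = np.cos(rot), np.sin(rot)
        v0 = 6.0 * np.array([c * aim[0] - s * aim[1], s * aim[0] + c * aim[1]])
        traj = run_sim(
            times, tpos, tvel, speed,
            GuidanceParams(GuidanceLaw.BACKGROUND_PN, N=1.0, tau=0.0),
            self.dt, r0, v0, t_end=1.2,
        )
        assert np.all(traj.turn_rates == 0.0)
        chord = traj.positions[-1] - traj.positions[0]
        u = chord / np.linalg.norm(chord)
        lateral = (traj.positions - traj.positions[0]) @ np.array([-u[1], u[0]])
        assert np.max(np.abs(lateral)) < 1e-9
        delta = track_deviation(traj, tpos)
        assert abs(delta[-1]) >= abs(delta[0])  # no convergence

    @pytest.mark.parametrize(
        "params, shrink",
        [
            # PP damps the deviation angle at rate K, fast
            (GuidanceParams(GuidanceLaw.PP, K=5.0, tau=0.0), 0.05),
            # inertial-PN corrects misdirection like target motion; with
            # N > 1 the deviation decays at the slower rate (N-1) |λ̇|
            (GuidanceParams(GuidanceLaw.INERTIAL_PN, N=1.5, tau=0.0), 0.6),
        ],
    )
    def test_heading_error_feedback_converges_deviation(self, params, shrink):
        """From the same 30-degree misdirection, PP and inertial-PN steer
        the deviation angle toward zero (background-PN, above, does not)."""
        times, tpos, tvel = straight_target(self.dt, 2.0)
        speed = np.full(len(times), 6.0)
        r0 = np.array([0.0, 0.0])
        aim = (tpos[0] - r0) / np.linalg.norm(tpos[0] - r0)
        rot = np.deg2rad(30)
        c, s = np.cos(rot), np.sin(rot)
        v0 = 6.0 * np.array([c * aim[0] - s * aim[1], s * aim[0] + c * aim[1]])
        traj = run_sim(times, tpos, tvel, speed, params, self.dt, r0, v0, t_end=1.2)
        delta = np.abs(track_deviation(traj, tpos))
        assert delta[-1] < shrink * delta[0]
        assert np.all(np.diff(delta) <= 1e-12)  # monotone decay

    def test_speed_matching_follows_measured_profile(self):
        """|v[n+1]| equals the measured speed at step n (the recursion's
        printed indexing) to relative precision 1e-12."""
        times, tpos, tvel = straight_target(self.dt, 1.0, vel=(3.0, 1.0))
        rng = np.random.default_rng(1)
        speed = 6.0 + rng.uniform(-1, 1, len(times)).cumsum() * 0.01
        traj = run_sim(
            times, tpos, tvel, speed,
            GuidanceParams(GuidanceLaw.INERTIAL_PNP, N=0.8, K=2.4, tau=0.0),
            self.dt, [0.0, 0.0], [6.0, 0.5],
        )
        sim_speed = np.linalg.norm(traj.velocities[1:], axis=1)
        assert np.all(np.abs(sim_speed - speed[: len(times) - 1]) < 1e-12 * speed[:-1])

    def test_mixed_law_reduces_exactly_to_pn_and_pp(self):
        times, tpos, tvel = straight_target(self.dt, 1.5, vel=(4.0, -1.0))
        speed = np.full(len(times), 7.0)
        args = (times, tpos, tvel, speed)
        kw = dict(dt=self.dt, r0=[0.0, 0.0], v0=[6.0, 2.0])
        pnp_k0 = run_sim(*args, GuidanceParams(GuidanceLaw.INERTIAL_PNP, N=0.9, K=0.0, tau=0.01), **kw)
        pn = run_sim(*args, GuidanceParams(GuidanceLaw.INERTIAL_PN, N=0.9, K=7.7, tau=0.01), **kw)
        assert np.array_equal(pnp_k0.positions, pn.positions)
        pnp_n0 = run_sim(*args, GuidanceParams(GuidanceLaw.BACKGROUND_PNP, N=0.0, K=3.0, tau=0.01), **kw)
        pp = run_sim(*args, GuidanceParams(GuidanceLaw.PP, N=9.9, K=3.0, tau=0.01), **kw)
        assert np.array_equal(pnp_n0.positions, pp.positions)

    def test_matches_independent_reference_recursion(self, reference_simulator):
        """The compiled kernel reproduces a plain-Python implementation of
        the same difference equations."""
        dt = 1e-3
        m = 800
        t = np.arange(m) * dt
        tpos = np.column_stack([8.0 + 5.0 * t, 3.0 + 0.8 * np.sin(4.0 * t)])
        tvel = np.column_stack([np.full(m, 5.0), 0.8 * 4.0 * np.cos(4.0 * t)])
        speed = np.full(m, 9.0)
        params = GuidanceParams(GuidanceLaw.INERTIAL_PNP, N=0.8, K=2.4, tau=0.02)
        r0, v0 = np.zeros(2), np.array([9.0, 0.0])
        traj = run_sim(t, tpos, tvel, speed, params, dt, r0, v0)
        ref = reference_simulator(tpos, tvel, speed, r0, v0, params, dt, d=20)
        assert np.allclose(traj.positions, ref, atol=1e-9)

    def test_euler_convergence_first_order(self):
        """Halving the step roughly halves the end-point discretisation
        error, as expected for forward Euler."""
        finals = {}
        for dt in (2e-3, 1e-3, 5e-4):
            times, tpos, tvel = straight_target(dt, 1.0)
            speed = np.full(len(times), 6.0)
            traj = run_sim(
                times, tpos, tvel, speed,
                GuidanceParams(GuidanceLaw.PP, K=3.0, tau=0.0),
                dt, [0.0, 0.0], [5.0, 3.3],
            )
            finals[dt] = traj.positions[-1]
        d1 = np.linalg.norm(finals[2e-3] - finals[1e-3])
        d2 = np.linalg.norm(finals[1e-3] - finals[5e-4])
        assert 1.4 < d1 / d2 < 2.8

    def test_input_validation(self):
        times, tpos, tvel = straight_target(self.dt, 0.5)
        speed = np.full(len(times), 6.0)
        with pytest.raises(ValueError, match="multiple"):
            run_sim(
                times, tpos, tvel, speed,
                GuidanceParams(GuidanceLaw.PP, K=1.0, tau=0.0007),
                self.dt, [0.0, 0.0], [6.0, 0.0],
            )
        with pytest.raises(InputCoverageError):
            run_sim(
                times, tpos, tvel, speed,
                GuidanceParams(GuidanceLaw.PP, K=1.0, tau=0.0),
                self.dt, [0.0, 0.0], [6.0, 0.0], t_end=2.0,
            )
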