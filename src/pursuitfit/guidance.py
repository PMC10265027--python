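"""Guidance laws and the speed-matched pursuit simulator.

Five candidate guidance laws command the pursuer's inertial turn rate from
delayed feedback of the line-of-sight rate and/or the deviation angle:

=================  =====================================  ==================
law                turn-rate command                      feedback
=================  =====================================  ==================
PP                 -K * delta(t - tau)                    deviation angle
inertial-PN         N * ilos(t - tau)                     inertial LOS rate
background-PN       N * blos(t - tau)                     background LOS rate
inertial-PNP        N * ilos(t - tau) - K * delta(t-tau)  both
background-PNP      N * blos(t - tau) - K * delta(t-tau)  both
=================  =====================================  ==================

N is a dimensionless navigation gain, K a pursuit gain (1/s) and tau a fixed
sensorimotor delay (s). The commanded centripetal acceleration is the turn
rate times the +90-degree rotation of the pursuer velocity, so it is always
perpendicular to the flight path; the pursuer's speed is constrained to a
measured speed profile and only its heading is governed by the law.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import _engine
from .geometry import GeometryError, rotate90


class GuidanceLaw(str, enum.Enum):
    PP = "pp"
    INERTIAL_PN = "inertial_pn"
    BACKGROUND_PN = "background_pn"
    INERTIAL_PNP = "inertial_pnp"
    BACKGROUND_PNP = "background_pnp"

    @property
    def uses_n(self) -> bool:
        return self is not GuidanceLaw.PP

    @property
    def uses_k(self) -> bool:
        return self in (GuidanceLaw.PP, GuidanceLaw.INERTIAL_PNP, GuidanceLaw.BACKGROUND_PNP)

    @property
    def uses_background(self) -> bool:
        return self in (GuidanceLaw.BACKGROUND_PN, GuidanceLaw.BACKGROUND_PNP)

    @property
    def n_gains(self) -> int:
        return int(self.uses_n) + int(self.uses_k)


@dataclass(frozen=True)
class GuidanceParams:
    """A guidance hypothesis: the law plus its gains and delay.

    ``N`` is ignored (treated as 0) for PP and ``K`` is ignored for the pure
    PN laws, mirroring the fact that those laws are the N=0 / K=0 special
    cases of the mixed law.
    """

    law: GuidanceLaw
    N: float = 0.0
    K: float = 0.0
    tau: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.N, self.K, self.tau]).all():
            raise ValueError("guidance parameters must be finite")
        if self.tau < 0:
            raise ValueError("delay tau must be non-negative")

    @property
    def n_eff(self) -> float:
        return self.N if self.law.uses_n else 0.0

    @property
    def k_eff(self) -> float:
        return self.K if self.law.uses_k else 0.0


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for the forward-Euler simulator.

    dt is the integration step (default 5e-5 s, i.e. 20 kHz); tau_max bounds
    the fitted delay and fixes the simulation start time t_start = tau_max so
    that measured pursuer states exist on [t_start - tau_max, t_start] for
    every admissible delay. Delays must be integer multiples of dt.
    """

    dt: float = 5e-5
    tau_max: float = 0.15
    t_start: float | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_max < 0:
            raise ValueError("tau_max must be non-negative")

    @property
    def start_time(self) -> float:
        return self.tau_max if self.t_start is None else self.t_start

    def delay_steps(self, tau: float) -> int:
        d = int(round(tau / self.dt))
        if abs(d * self.dt - tau) > 1e-9:
            raise ValueError(
                f"delay tau={tau} is not an integer multiple of dt={self.dt}"
            )
        return d


@dataclass
class SimTrajectory:
    """Simulated pursuer track on the dense time grid [t_start, t_end]."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    turn_rates: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


class InputCoverageError(ValueError):
    """Raised when target/speed data do not cover the simulation window."""


def commanded_turn_rate(
    params: GuidanceParams, delayed_los_rate: float, delayed_delta: float
) -> float:
    """Scalar turn-rate command (rad/s) for delayed feedback values."""
    return params.n_eff * delayed_los_rate - params.k_eff * delayed_delta


def commanded_acceleration(
    params: GuidanceParams,
    delayed_los_rate: float,
    delayed_delta: float,
    v_p: np.ndarray,
) -> np.ndarray:
    """Commanded centripetal acceleration (m/s^2), perpendicular to v_p.

    ``a = (N * los_rate - K * delta) * R90(v_p)`` where the delayed feedback
    values are evaluated at t - tau by the caller.
    """
    v_p = np.asarray(v_p, dtype=float)
    if np.any(np.hypot(v_p[..., 0], v_p[..., 1]) == 0.0):
        raise GeometryError("commanded acceleration undefined for zero velocity")
    g = commanded_turn_rate(params, delayed_los_rate, delayed_delta)
    return g * rotate90(v_p)


def _check_dense(times: np.ndarray, dt: float) -> None:
    if len(times) < 2:
        raise InputCoverageError("dense track needs at least two samples")
    steps = np.diff(times)
    if np.any(np.abs(steps - dt) > 1e-9):
        raise InputCoverageError("dense track is not uniformly sampled at dt")


_STATUS_MSG = {
    _engine.ERR_COINCIDENT: "pursuer and target coincident during simulation",
    _engine.ERR_ZERO_SPEED: "pursuer velocity collapsed to zero during simulation",
}


def simulate_pursuit(
    times: np.ndarray,
    target_pos: np.ndarray,
    target_vel: np.ndarray,
    pursuer_speed: np.ndarray,
    measured_pursuer_pos: np.ndarray,
    measured_pursuer_vel: np.ndarray,
    params: GuidanceParams,
    cfg: SimConfig,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    t_end: float | None = None,
) -> SimTrajectory:
    """Simulate the pursuer under a guidance law against a measured target.

    All input arrays live on a common dense time grid starting at t = 0 (the
    onset of target motion) with uniform spacing ``cfg.dt``. The simulation
    runs from ``cfg.start_time`` (default tau_max) to ``t_end`` (default the
    end of the grid). The initial state defaults to the measured pursuer
    position/velocity at the start time; delayed feedback before the start
    time is computed from the measured pursuer states, as in the fitting
    protocol where data always exist on [0, tau_max].

    Raises
    ------
    InputCoverageError
        If the dense arrays do not cover the simulation window.
    GeometryError
        If pursuer and target coincide or the velocity degenerates.
    """
    times = np.asarray(times, dtype=float)
    target_pos = np.ascontiguousarray(target_pos, dtype=float)
    target_vel = np.ascontiguousarray(target_vel, dtype=float)
    pursuer_speed = np.ascontiguousarray(pursuer_speed, dtype=float)
    mpos = np.ascontiguousarray(measured_pursuer_pos, dtype=float)
    mvel = np.ascontiguousarray(measured_pursuer_vel, dtype=float)
    _check_dense(times, cfg.dt)
    if not (len(times) == len(target_pos) == len(target_vel) == len(pursuer_speed)):
        raise InputCoverageError("dense arrays have inconsistent lengths")

    t0 = times[0]
    i0 = int(round((cfg.start_time - t0) / cfg.dt))
    if i0 < 0 or i0 >= len(times):
        raise InputCoverageError("start time outside the supplied dense grid")
    i_end = len(times) - 1 if t_end is None else int(round((t_end - t0) / cfg.dt))
    if i_end > len(times) - 1 or i_end <= i0:
        raise InputCoverageError("end time outside the supplied dense grid")
    if i0 > 0 and (len(mpos) < i0 or len(mvel) < i0):
        raise InputCoverageError(
            "measured pursuer states must cover [0, t_start) for delayed feedback"
        )

    d = cfg.delay_steps(params.tau)
    md, ml = _engine.measured_delta_los(
        target_pos, target_vel, mpos, mvel, i0, params.law.uses_background
    )
    if init is None:
        if len(mpos) <= i0 or len(mvel) <= i0:
            raise InputCoverageError(
                "measured pursuer states must include t_start to set initial conditions"
            )
        r0 = mpos[i0]
        v0 = mvel[i0]
    else:
        r0 = np.asarray(init[0], dtype=float)
        v0 = np.asarray(init[1], dtype=float)

    pos, vel, gdot, status = _engine.simulate_traj(
        target_pos,
        target_vel,
        pursuer_speed,
        md,
        ml,
        i0,
        i_end,
        d,
        cfg.dt,
        params.n_eff,
        params.k_eff,
        params.law.uses_background,
        float(r0[0]),
        float(r0[1]),
        float(v0[0]),
        float(v0[1]),
    )
    if status != _engine.OK:
        raise GeometryError(_STATUS_MSG[status])
    return SimTrajectory(times[i0 : i_end + 1].copy(), pos, vel, gdot)
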