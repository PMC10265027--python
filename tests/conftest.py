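import numpy as np
import pytest
from hypothesis import settings

import pursuitfit as pf
from pursuitfit.guidance import GuidanceLaw, GuidanceParams, SimConfig

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

# scaled-down study conditions used throughout the suite: 1 ms dense step
# (every tau-grid value remains an integer number of steps) instead of the
# production 20 kHz grid, so a full parameter grid evaluates in seconds
DT = 1e-3


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(dt=DT)


def _cohort(law, N, K, tau, n, seed, noise=0.0, require_intercept=True):
    spec = pf.SyntheticSpec(
        seed=seed,
        dt=DT,
        noise_sigma=noise,
        guidance=GuidanceParams(law, N=N, K=K, tau=tau),
        require_intercept=require_intercept,
    )
    return pf.generate_cohort(spec, n)


@pytest.fixture(scope="session")
def ipn_cohort():
    """Four noise-free flights generated under inertial-PN at a grid point."""
    return _cohort(GuidanceLaw.INERTIAL_PN, 1.0, 0.0, 0.055, 4, seed=3)


@pytest.fixture(scope="session")
def ipn_grid(ipn_cohort, sim_cfg):
    return pf.build_error_grid(ipn_cohort, GuidanceLaw.INERTIAL_PN, sim_cfg)


@pytest.fixture(scope="session")
def ipnp_cohort():
    """Four noise-free flights under inertial-PNP at a grid point."""
    return _cohort(GuidanceLaw.INERTIAL_PNP, 0.8, 2.4, 0.005, 4, seed=11)


@pytest.fixture(scope="session")
def ipnp_grid(ipnp_cohort, sim_cfg):
    return pf.build_error_grid(ipnp_cohort, GuidanceLaw.INERTIAL_PNP, sim_cfg)


@pytest.fixture(scope="session")
def reference_simulator():
    """Independent plain-Python forward-Euler pursuit recursion.

    Kept deliberately separate from the package's compiled kernel so the two
    routes check each other.
    """

    def simulate(target_pos, target_vel, speed, r0, v0, params, dt, d, i0=0,
                 meas_delta=None, meas_los=None):
        import math

        rx, ry = float(r0[0]), float(r0[1])
        vx, vy = float(v0[0]), float(v0[1])
        n = len(target_pos) - i0
        out = np.empty((n, 2))
        hd, hl = [], []
        bg = params.law.uses_background
        for k in range(n):
            i = i0 + k
            lx = target_pos[i][0] - rx
            ly = target_pos[i][1] - ry
            r2 = lx * lx + ly * ly
            delta = math.atan2(lx * vy - ly * vx, lx * vx + ly * vy)
            if bg:
                los = (lx * target_vel[i][1] - ly * target_vel[i][0]) / r2
            else:
                los = (lx * (target_vel[i][1] - vy) - ly * (target_vel[i][0] - vx)) / r2
            hd.append(delta)
            hl.append(los)
            j = max(i - d, 0)
            if j < i0:
                dd, dl = meas_delta[j], meas_los[j]
            else:
                dd, dl = hd[j - i0], hl[j - i0]
            g = params.n_eff * dl - params.k_eff * dd
            out[k] = (rx, ry)
            if k < n - 1:
                ax, ay = -g * vy, g * vx
                nrx, nry = rx + dt * vx, ry + dt * vy
                tvx, tvy = vx + dt * ax, vy + dt * ay
                nv = math.hypot(tvx, tvy)
                s = speed[i]
                vx, vy = s * tvx / nv, s * tvy / nv
                rx, ry = nrx, nry
        return out

    return simulate


def straight_target(dt, duration, pos=(8.0, 3.0), vel=(0.0, 0.0)):
    """Dense track of a target moving uniformly (or stationary)."""
    m = int(round(duration / dt)) + 1
    t = np.arange(m) * dt
    p = np.asarray(pos, float) + t[:, None] * np.asarray(vel, float)
    v = np.tile(np.asarray(vel, float), (m, 1))
    return t, p, v
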