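"""Numba kernels for the speed-matched forward-Euler pursuit simulator.

The discrete-time recursion is, per step n (step size dt):

    r[n+1] = r[n] + dt * v[n]
    v[n+1] = s[n] * (v[n] + dt * a[n]) / |v[n] + dt * a[n]|

where ``s[n]`` is the measured pursuer speed at step n (speed matching: the
guidance law only governs heading) and ``a[n]`` is the commanded centripetal
acceleration ``(N * los_rate(t - tau) - K * delta(t - tau)) x v[n]``
realised as a +90-degree rotation of ``v[n]`` scaled by the commanded turn
rate. Delayed quantities are read from the simulated history when
``t - tau >= t_start`` and from the supplied measured pursuer states before
that; when the simulation itself starts at t = 0 (synthetic generation) the
delayed index is clamped to the first simulated step.

Two kernels share the identical per-step arithmetic: ``simulate_traj``
records the full trajectory of a single parameter set, while ``rms_batch``
evaluates many (N, K) parameter sets at one delay and accumulates only the
RMS position error at the measurement frames. Keeping the arithmetic
identical makes the two routes bit-compatible, which the tests rely on.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

# error codes shared by the kernels (numba cannot raise rich exceptions)
OK = 0
ERR_COINCIDENT = 1
ERR_ZERO_SPEED = 2


@nb.njit(cache=False)
def _delta_los(rx, ry, vtx, vty, vpx, vpy, background):
    """Deviation angle and line-of-sight rate for one state.

    Returns (delta, los_rate, r2). r2 == 0 signals degenerate geometry.
    """
    r2 = rx * rx + ry * ry
    if r2 == 0.0:
        return 0.0, 0.0, 0.0
    delta = math.atan2(rx * vpy - ry * vpx, rx * vpx + ry * vpy)
    if background:
        los = (rx * vty - ry * vtx) / r2
    else:
        los = (rx * (vty - vpy) - ry * (vtx - vpx)) / r2
    return delta, los, r2


@nb.njit(cache=False)
def measured_delta_los(tpos, tvel, mpos, mvel, i0, background):
    """Deviation angle / LOS rate of the measured pursuer on [0, i0)."""
    md = np.empty(i0)
    ml = np.empty(i0)
    for i in range(i0):
        d, l, r2 = _delta_los(
            tpos[i, 0] - mpos[i, 0],
            tpos[i, 1] - mpos[i, 1],
            tvel[i, 0],
            tvel[i, 1],
            mvel[i, 0],
            mvel[i, 1],
            background,
        )
        md[i] = d
        ml[i] = l
    return md, ml


@nb.njit(cache=False)
def simulate_traj(
    tpos,
    tvel,
    speed,
    meas_delta,
    meas_los,
    i0,
    i_end,
    d,
    dt,
    N,
    K,
    background,
    r0x,
    r0y,
    v0x,
    v0y,
):
    """Simulate one pursuer trajectory on dense indices [i0, i_end].

    Returns (pos, vel, turn_rate, status).
    """
    n = i_end - i0 + 1
    pos = np.empty((n, 2))
    vel = np.empty((n, 2))
    gdot = np.empty(n)
    hd = np.empty(n)
    hl = np.empty(n)
    rx, ry, vx, vy = r0x, r0y, v0x, v0y
    for k in range(n):
        i = i0 + k
        delta, los, r2 = _delta_los(
            tpos[i, 0] - rx, tpos[i, 1] - ry, tvel[i, 0], tvel[i, 1], vx, vy, background
        )
        if r2 == 0.0:
            return pos, vel, gdot, ERR_COINCIDENT
        hd[k] = delta
        hl[k] = los
        j = i - d
        if j < 0:
            j = 0
        if j < i0:
            dd = meas_delta[j]
            dl = meas_los[j]
        else:
            dd = hd[j - i0]
            dl = hl[j - i0]
        g = N * dl - K * dd
        pos[k, 0] = rx
        pos[k, 1] = ry
        vel[k, 0] = vx
        vel[k, 1] = vy
        gdot[k] = g
        if k < n - 1:
            ax = -g * vy
            ay = g * vx
            nrx = rx + dt * vx
            nry = ry + dt * vy
            tvx = vx + dt * ax
            tvy = vy + dt * ay
            nv = math.sqrt(tvx * tvx + tvy * tvy)
            if nv == 0.0:
                return pos, vel, gdot, ERR_ZERO_SPEED
            s = speed[i]
            vx = s * tvx / nv
            vy = s * tvy / nv
            rx = nrx
            ry = nry
    return pos, vel, gdot, OK


@nb.njit(cache=False)
def rms_batch(
    tpos,
    tvel,
    speed,
    meas_delta,
    meas_los,
    i0,
    i_end,
    d,
    dt,
    Ns,
    Ks,
    background,
    frame_k,
    frame_pos,
    r0x,
    r0y,
    v0x,
    v0y,
):
    """RMS position error at the measurement frames for many (N, K) pairs.

    ``frame_k`` holds frame indices relative to i0 (sorted ascending);
    ``frame_pos`` the corresponding measured pursuer positions. A lane whose
    simulation degenerates scores +inf.
    """
    P = Ns.shape[0]
    n = i_end - i0 + 1
    nf = frame_k.shape[0]
    out = np.empty(P)
    hd = np.empty(n)
    hl = np.empty(n)
    for p in range(P):
        N = Ns[p]
        K = Ks[p]
        rx, ry, vx, vy = r0x, r0y, v0x, v0y
        acc = 0.0
        fptr = 0
        failed = False
        for k in range(n):
            i = i0 + k
            delta, los, r2 = _delta_los(
                tpos[i, 0] - rx,
                tpos[i, 1] - ry,
                tvel[i, 0],
                tvel[i, 1],
                vx,
                vy,
                background,
            )
            if r2 == 0.0:
                failed = True
                break
            hd[k] = delta
            hl[k] = los
            if fptr < nf and frame_k[fptr] == k:
                dx = rx - frame_pos[fptr, 0]
                dy = ry - frame_pos[fptr, 1]
                acc += dx * dx + dy * dy
                fptr += 1
            j = i - d
            if j < 0:
                j = 0
            if j < i0:
                dd = meas_delta[j]
                dl = meas_los[j]
            else:
                dd = hd[j - i0]
                dl = hl[j - i0]
            g = N * dl - K * dd
            if k < n - 1:
                ax = -g * vy
                ay = g * vx
                nrx = rx + dt * vx
                nry = ry + dt * vy
                tvx = vx + dt * ax
                tvy = vy + dt * ay
                nv = math.sqrt(tvx * tvx + tvy * tvy)
                if nv == 0.0:
                    failed = True
                    break
                s = speed[i]
                vx = s * tvx / nv
                vy = s * tvy / nv
                rx = nrx
                ry = nry
        if failed or fptr == 0:
            out[p] = np.inf
        else:
            out[p] = math.sqrt(acc / nf)
    return out
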