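"""Synthetic chase data with the statistical structure of the lure task.

The generator emulates the experimental protocol: a lure towed along an
unpredictable zigzag course across a 20.2 x 6.1 m arena at a constant speed
drawn from 6-8 m/s, a hawk launched from one of three perch positions and
steered by a known guidance law with a prescribed (speed-matched) flight
speed profile, 200 Hz sampling with additive isotropic Gaussian position
noise, and raw marker clouds with rigid-template markers, occlusion dropout
and spurious spike points. Every generator is a pure function of its spec
and seed, and the ground truth (dense trajectory, marker labels, generating
parameters) is retained for testing parameter recovery end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _engine
from .flight import Flight, FRAME_RATE, INTERCEPT_RADIUS
from .guidance import GuidanceLaw, GuidanceParams
from .preprocess import MarkerCloud, Template

ARENA = (20.2, 6.1)  # m
HAWK_STARTS = ((0.6, 1.2), (0.6, 3.05), (0.6, 4.9))  # three perch positions


class NoInterceptError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic chase.

    Defaults reproduce the recording conditions the analysis assumes: the
    arena floor, the lure speed band, 200 Hz sampling and a 20 kHz dense
    grid. ``noise_sigma`` is the isotropic per-axis position noise of the
    200 Hz observations; ``occlusion_rate`` the per-marker dropout
    probability; spike points appear per frame with ``spike_rate`` at up to
    ``spike_magnitude`` from the true position.
    """

    seed: int = 0
    arena: tuple[float, float] = ARENA
    lure_speed_range: tuple[float, float] = (6.0, 8.0)
    n_turns: int = 4
    guidance: GuidanceParams = GuidanceParams(GuidanceLaw.INERTIAL_PN, N=1.0, tau=0.055)
    hawk_start: int | None = None  # 0..2, None draws one of the three perches
    noise_sigma: float = 0.001  # m, per-axis mocap noise at 200 Hz
    occlusion_rate: float = 0.05
    spike_rate: float = 0.02
    spike_magnitude: float = 0.6  # m
    dt: float = 5e-5  # dense integration/sampling step (20 kHz)
    frame_rate: float = FRAME_RATE
    hawk_cruise_speed: float = 10.0  # m/s
    hawk_launch_speed: float = 2.0  # m/s
    hawk_ramp_time: float = 0.5  # s to reach cruise
    hawk_height: float = 0.7  # m, constant flight height for markers
    lure_height: float = 0.05  # m
    corner_radius: float = 0.2  # m, lure path fillet radius
    tail_time: float = 4.0  # s the lure dwells at the course end
    time_cap: float = 10.0  # s, generation aborts without an intercept
    flare_range: float = 4.0  # m: range at which the hawk starts decelerating
    flare_decel: float = 12.0  # m/s^2 rate limit on the terminal braking
    flare_gain: float = 3.0  # 1/s: flared speed tracks flare_gain * range
    flare_floor: float = 0.10  # m/s minimum flight speed during the grab
    grab_time: float = 0.15  # s of recording retained past first contact
    require_intercept: bool = True  # if False, crop at closest approach instead


@dataclass
class LureTrack:
    """Dense lure course sampled at the integration step."""

    times: np.ndarray
    pos: np.ndarray  # (M, 2)
    vel: np.ndarray  # (M, 2)
    speed: float
    waypoints: np.ndarray


def _fillet_path(waypoints: np.ndarray, radius: float):
    """Piecewise line/arc path through waypoints with rounded corners.

    Returns a list of elements; each is ('line', a, b, length) or
    ('arc', center, radius, a0, sweep, length) with signed sweep.
    """
    elements = []
    cursor = waypoints[0]
    for i in range(1, len(waypoints) - 1):
        p_prev, p, p_next = waypoints[i - 1], waypoints[i], waypoints[i + 1]
        u_in = (p - p_prev) / np.linalg.norm(p - p_prev)
        u_out = (p_next - p) / np.linalg.norm(p_next - p)
        cosphi = float(np.clip(u_in @ u_out, -1.0, 1.0))
        phi = math.acos(cosphi)
        if phi < 1e-6:  # straight through
            continue
        rho = radius
        t_len = rho * math.tan(phi / 2)
        limit = 0.45 * min(np.linalg.norm(p - p_prev), np.linalg.norm(p_next - p))
        if t_len > limit:
            t_len = limit
            rho = t_len / math.tan(phi / 2)
        a = p - t_len * u_in
        b = p + t_len * u_out
        sgn = 1.0 if (u_in[0] * u_out[1] - u_in[1] * u_out[0]) > 0 else -1.0
        center = a + rho * sgn * np.array([-u_in[1], u_in[0]])
        seg_len = float(np.linalg.norm(a - cursor))
        if seg_len > 0:
            elements.append(("line", cursor.copy(), a.copy(), seg_len))
        a0 = math.atan2(a[1] - center[1], a[0] - center[0])
        elements.append(("arc", center, rho, a0, sgn * phi, rho * phi))
        cursor = b
    seg_len = float(np.linalg.norm(waypoints[-1] - cursor))
    if seg_len > 0:
        elements.append(("line", cursor.copy(), waypoints[-1].copy(), seg_len))
    return elements


def _path_state(elements, s: np.ndarray):
    """Position and unit tangent along the path at arc lengths s."""
    pos = np.empty((len(s), 2))
    tan = np.empty((len(s), 2))
    bounds = np.cumsum([e[-1] for e in elements])
    starts = bounds - np.array([e[-1] for e in elements])
    idx = np.minimum(np.searchsorted(bounds, s, side="right"), len(elements) - 1)
    for ei in range(len(elements)):
        sel = idx == ei
        if not sel.any():
            continue
        sl = s[sel] - starts[ei]
        e = elements[ei]
        if e[0] == "line":
            _, a, b, length = e
            u = (b - a) / length
            pos[sel] = a + sl[:, None] * u
            tan[sel] = u
        else:
            _, center, rho, a0, sweep, length = e
            ang = a0 + np.sign(sweep) * sl / rho
            pos[sel] = center + rho * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
            tdir = np.stack([-np.sin(ang), np.cos(ang)], axis=-1) * np.sign(sweep)
            tan[sel] = tdir
    return pos, tan


def generate_lure_course(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> LureTrack:
    """Draw a zigzag lure course and sample it densely at constant speed.

    The course starts from a hidden point near the hawk's end of the arena
    and zigzags between two lateral bands while advancing down the hall,
    with circular fillets standing in for the pulley corners. Motion starts
    at t = 0; after reaching the course end the lure remains stationary for
    ``tail_time`` seconds.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    ax, ay = spec.arena
    margin = 0.7
    speed = float(rng.uniform(*spec.lure_speed_range))
    low = (0.8, 1.6)
    high = (ay - 1.6, ay - 0.8)
    band = int(rng.integers(2))

    n_way = spec.n_turns + 2
    n_seg = n_way - 1
    x0 = float(rng.uniform(2.0, 3.5))
    max_x = ax - margin
    budget = max_x - x0 - 2.0 * n_seg  # advance beyond the 2 m minimum per segment
    if budget < 0:
        raise ValueError("arena too small for the requested number of turns")
    u = rng.uniform(0.2, 1.0, n_seg)
    dx = 2.0 + u / u.sum() * float(rng.uniform(0.3, 1.0)) * budget
    xs = x0 + np.concatenate([[0.0], np.cumsum(dx)])
    points = []
    for i in range(n_way):
        lo, hi = (low, high)[band]
        points.append((float(xs[i]), float(rng.uniform(lo, hi))))
        band ^= 1
    waypoints = np.asarray(points)

    elements = _fillet_path(waypoints, spec.corner_radius)
    total = float(sum(e[-1] for e in elements))
    move_time = total / speed
    duration = min(move_time + spec.tail_time, spec.time_cap)
    m = int(round(duration / spec.dt)) + 1
    times = np.arange(m) * spec.dt
    s = np.minimum(times * speed, total)
    pos, tan = _path_state(elements, s)
    vel = speed * tan
    vel[times * speed >= total] = 0.0
    return LureTrack(times, np.ascontiguousarray(pos), np.ascontiguousarray(vel), speed, waypoints)


def generate_hawk_flight(
    lure: LureTrack,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    flight_id: str = "synth-000",
) -> Flight:
    """Simulate the hawk under the spec's guidance law and observe at 200 Hz.

    The hawk launches at t = 0 from one of the three perch positions with
    its velocity aimed at the lure, follows a trapezoidal speed profile
    (ramp to cruise), and the flight ends at the first approach within the
    intercept radius. Observed 200 Hz frames are the true positions plus
    isotropic Gaussian noise; the dense truth is retained on the Flight.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    params = spec.guidance
    dt = spec.dt
    m = len(lure.times)

    ramp = np.minimum(lure.times / spec.hawk_ramp_time, 1.0)
    base = spec.hawk_launch_speed + (spec.hawk_cruise_speed - spec.hawk_launch_speed) * ramp

    start_i = int(rng.integers(3)) if spec.hawk_start is None else int(spec.hawk_start)
    r0 = np.asarray(HAWK_STARTS[start_i], dtype=float)
    aim = lure.pos[0] - r0
    dist0 = np.linalg.norm(aim)
    if dist0 == 0:
        raise ValueError("hawk start coincides with the lure start")

    d = int(round(params.tau / dt))
    if abs(d * dt - params.tau) > 1e-9:
        raise ValueError("guidance delay must be an integer multiple of dt")
    empty = np.empty(0)

    def run(speed_profile):
        v0 = speed_profile[0] * aim / dist0
        pos, vel, gdot, status = _engine.simulate_traj(
            lure.pos,
            lure.vel,
            speed_profile,
            empty,
            empty,
            0,
            m - 1,
            d,
            dt,
            params.n_eff,
            params.k_eff,
            params.law.uses_background,
            r0[0],
            r0[1],
            v0[0],
            v0[1],
        )
        if status != _engine.OK:
            raise NoInterceptError("simulation degenerated before an intercept")
        dist = np.hypot(pos[:, 0] - lure.pos[:, 0], pos[:, 1] - lure.pos[:, 1])
        return pos, vel, dist

    # The steering law is applied unchanged throughout; the terminal grab is
    # emulated purely through the prescribed speed profile, which the
    # speed-matched refit reproduces exactly. Once the lure has stopped and
    # the hawk is within flare_range, the flight speed tracks
    # flare_gain * range (rate-limited, floored), emulating the braking
    # flare of a landing grab. The profile is iterated to self-consistency.
    moving = np.hypot(lure.vel[:, 0], lure.vel[:, 1]) > 0
    i_stop = int(np.flatnonzero(~moving)[0]) if (~moving).any() else m

    # capture is decided at the measurement frames, matching the QC criterion
    stride = int(round(1.0 / (spec.frame_rate * dt)))
    f_all = np.arange(0, m, stride)

    def capture_frame(dist):
        hit = np.flatnonzero(dist[f_all] <= INTERCEPT_RADIUS)
        return int(f_all[hit[0]]) if len(hit) else -1

    speed = base.copy()
    pos, vel, dist = run(speed)
    for _ in range(6):
        if capture_frame(dist) >= 0:
            break
        cand = np.flatnonzero((dist <= spec.flare_range) & (np.arange(m) >= i_stop))
        if len(cand) == 0:
            break
        on = int(cand[0])
        target_v = np.clip(spec.flare_gain * dist, spec.flare_floor, base)
        new_speed = base.copy()
        prev = base[on]
        lim = spec.flare_decel * dt
        for i in range(on, m):
            tv = target_v[i]
            prev = min(max(tv, prev - lim), prev + lim)
            new_speed[i] = prev
        if np.allclose(new_speed, speed, atol=1e-9):
            break
        speed = new_speed
        pos, vel, dist = run(speed)

    ic = capture_frame(dist)
    if ic >= 0:
        intercepted = True
    elif spec.require_intercept:
        raise NoInterceptError(
            f"no intercept within the {lure.times[-1]:.1f} s generation cap"
        )
    else:
        ic = int(f_all[np.argmin(dist[f_all])])  # frame-aligned closest approach
        intercepted = False
        if lure.times[ic] <= 0.5:
            raise NoInterceptError("closest approach too early to define a flight")

    # the recording continues briefly past first contact (the grab), as a
    # real capture session would; the intercept time stays at first contact
    ic_keep = min(ic + int(round(spec.grab_time / dt / stride)) * stride, int(f_all[-1]))
    frame_idx = np.arange(0, ic_keep + 1, stride)
    frame_times = lure.times[frame_idx]
    hawk_truth = pos[frame_idx]
    lure_truth = lure.pos[frame_idx]
    hawk_frames = hawk_truth.copy()
    lure_frames = lure_truth.copy()
    if spec.noise_sigma > 0:
        hawk_frames = hawk_frames + rng.normal(0.0, spec.noise_sigma, hawk_frames.shape)
        lure_frames = lure_frames + rng.normal(0.0, spec.noise_sigma, lure_frames.shape)

    return Flight(
        flight_id=flight_id,
        dt=dt,
        times=lure.times[: ic_keep + 1].copy(),
        hawk_pos=pos[: ic_keep + 1],
        hawk_vel=vel[: ic_keep + 1],
        hawk_speed=speed[: ic_keep + 1].copy(),
        lure_pos=lure.pos[: ic_keep + 1].copy(),
        lure_vel=lure.vel[: ic_keep + 1].copy(),
        frame_times=frame_times,
        hawk_frames=hawk_frames,
        lure_frames=lure_frames,
        intercept_time=float(lure.times[ic]),
        meta={
            "seed": spec.seed,
            "law": params.law.value,
            "N": params.N,
            "K": params.K,
            "tau": params.tau,
            "lure_speed": lure.speed,
            "hawk_start": start_i,
            "noise_sigma": spec.noise_sigma,
            "intercepted": intercepted,
            "hawk_frames_truth": hawk_truth,
            "lure_frames_truth": lure_truth,
        },
    )


def generate_flight(spec: SyntheticSpec, flight_id: str = "synth-000") -> Flight:
    """Lure course plus guided hawk flight from a single seeded stream."""
    rng = np.random.default_rng(spec.seed)
    lure = generate_lure_course(spec, rng)
    return generate_hawk_flight(lure, spec, rng, flight_id=flight_id)


def generate_cohort(spec: SyntheticSpec, n_flights: int, max_attempts: int = 10) -> list[Flight]:
    """Generate n flights with distinct courses, retrying rare non-intercepts.

    Flight i uses the seed sequence (spec.seed, i, attempt), so cohorts are
    reproducible and flights are independent.
    """
    flights = []
    for i in range(n_flights):
        for attempt in range(max_attempts):
            rng = np.random.default_rng([spec.seed, i, attempt])
            try:
                lure = generate_lure_course(spec, rng)
                flights.append(
                    generate_hawk_flight(lure, spec, rng, flight_id=f"synth-{i:03d}")
                )
                break
            except NoInterceptError:
                continue
        else:
            raise NoInterceptError(
                f"flight {i}: no intercept in {max_attempts} attempts"
            )
    return flights


# rigid marker templates; offsets are in the body frame (x forward, m) and
# are chosen so the combined backpack + tail-mount centroid coincides with
# the tracked reference point
_BACKPACK_BASE = np.array(
    [
        [0.030, 0.012, 0.020],
        [-0.020, 0.030, 0.010],
        [-0.035, -0.020, 0.015],
        [0.050, -0.025, 0.030],
    ]
)
_TRI_R = 0.05 / math.sqrt(3.0)
_TAILMOUNT_BASE = np.array(
    [
        [-0.130 + _TRI_R * math.cos(math.pi / 2), _TRI_R * math.sin(math.pi / 2), 0.010],
        [-0.130 + _TRI_R * math.cos(7 * math.pi / 6), _TRI_R * math.sin(7 * math.pi / 6), 0.010],
        [-0.130 + _TRI_R * math.cos(11 * math.pi / 6), _TRI_R * math.sin(11 * math.pi / 6), 0.010],
    ]
)
_COMBINED_MEAN = (4 * _BACKPACK_BASE.mean(axis=0) + 3 * _TAILMOUNT_BASE.mean(axis=0)) / 7.0
BACKPACK_OFFSETS = _BACKPACK_BASE - _COMBINED_MEAN
TAILMOUNT_OFFSETS = _TAILMOUNT_BASE - _COMBINED_MEAN

# three 6.4 mm markers on each long face of the lure body
LURE_OFFSETS = np.array(
    [[x, y, 0.0] for y in (0.02, -0.02) for x in (-0.06, 0.0, 0.06)]
)

STATIONARY_POINTS = np.array(
    [
        [0.3, 0.3, 0.30],
        [0.3, 5.8, 0.30],
        [10.0, 0.3, 0.30],
        [10.0, 5.8, 0.30],
        [19.8, 0.3, 0.30],
        [19.8, 5.8, 0.30],
    ]
)


def default_templates() -> list[Template]:
    return [
        Template.from_points("backpack", BACKPACK_OFFSETS),
        Template.from_points("tailmount", TAILMOUNT_OFFSETS),
    ]


def lure_template() -> Template:
    return Template.from_points("lure", LURE_OFFSETS)


def _headings(vel: np.ndarray) -> np.ndarray:
    """Heading angle per frame; frozen through standstill."""
    h = np.arctan2(vel[:, 1], vel[:, 0])
    moving = np.hypot(vel[:, 0], vel[:, 1]) > 1e-9
    if not moving.all():
        last = 0.0
        for i in range(len(h)):
            if moving[i]:
                last = h[i]
            else:
                h[i] = last
    return h


def _place_markers(center_xy, z, heading, offsets):
    c, s = math.cos(heading), math.sin(heading)
    rot = np.array([[c, -s], [s, c]])
    xy = center_xy + offsets[:, :2] @ rot.T
    zz = z + offsets[:, 2]
    return np.column_stack([xy, zz])


def generate_marker_cloud(
    flight: Flight,
    spec: SyntheticSpec,
    templates_offsets: dict[str, np.ndarray] | None = None,
) -> MarkerCloud:
    """Raw 200 Hz marker cloud for a flight, with ground-truth labels.

    Rigid marker sets ride the true hawk and lure trajectories (oriented by
    the velocity heading), stationary apparatus markers sit at fixed points,
    markers drop out independently at ``occlusion_rate``, and spurious spike
    points are injected at ``spike_rate`` per frame near the hawk or lure.
    """
    offsets = templates_offsets or {
        "backpack": BACKPACK_OFFSETS,
        "tailmount": TAILMOUNT_OFFSETS,
        "lure": LURE_OFFSETS,
    }
    rng = np.random.default_rng([spec.seed, 104729])
    fidx = flight.frame_dense_indices()
    hawk_head = _headings(flight.hawk_vel[fidx])
    lure_head = _headings(flight.lure_vel[fidx])
    times = flight.frame_times
    truth_hawk = flight.meta.get("hawk_frames_truth", flight.hawk_frames)
    truth_lure = flight.meta.get("lure_frames_truth", flight.lure_frames)

    frames, labels = [], []
    for fi in range(len(times)):
        pts, lab = [], []
        for p in STATIONARY_POINTS:
            if rng.random() >= spec.occlusion_rate:
                pts.append(p)
                lab.append("stationary")
        groups = [
            ("backpack", truth_hawk[fi], spec.hawk_height, hawk_head[fi], offsets["backpack"]),
            ("tailmount", truth_hawk[fi], spec.hawk_height, hawk_head[fi], offsets["tailmount"]),
            ("lure", truth_lure[fi], spec.lure_height, lure_head[fi], offsets["lure"]),
        ]
        for name, ctr, z, heading, offs in groups:
            placed = _place_markers(ctr, z, heading, offs)
            for p in placed:
                if rng.random() >= spec.occlusion_rate:
                    if spec.noise_sigma > 0:
                        p = p + rng.normal(0.0, spec.noise_sigma, 3)
                    pts.append(p)
                    lab.append(name)
        if rng.random() < spec.spike_rate:
            mag = rng.uniform(0.15, spec.spike_magnitude)
            ang = rng.uniform(0.0, 2 * math.pi)
            off = mag * np.array([math.cos(ang), math.sin(ang)])
            if rng.random() < 0.5:  # corrupt the lure track
                pts.append(np.array([*(truth_lure[fi] + off), spec.lure_height]))
            else:
                pts.append(np.array([*(truth_hawk[fi] + off), spec.hawk_height]))
            lab.append("spike")
        frames.append(np.asarray(pts, dtype=float).reshape(-1, 3))
        labels.append(np.asarray(lab, dtype="<U16"))
    return MarkerCloud(times.copy(), frames, labels)
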