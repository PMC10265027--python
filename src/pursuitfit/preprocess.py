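"""Motion-capture preprocessing: raw marker clouds to smooth, clean tracks.

The chain mirrors a standard rigid-template mocap workflow:

1. ``label_markers`` — classify each unlabelled 3D point per frame as
   stationary apparatus, lure (near the floor plane), a rigid-template bird
   marker (matched by pairwise distances), or unassigned.
2. ``compute_centroids`` — bird and lure centroid per frame; frames with too
   few contributing markers become missing data.
3. ``clean_trajectory`` — two-pass sliding-window outlier elimination
   (extreme then moderate outliers).
4. ``smooth_and_differentiate`` — cubic gap interpolation followed by a
   quintic smoothing spline with a residual-norm tolerance; positions,
   velocities and accelerations are evaluated analytically on a dense grid.
5. ``qc_and_crop`` — inclusion filters (template reconstruction fraction,
   successful intercept within 30 mm) and cropping to the chase window.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, UnivariateSpline

from .flight import Flight, INTERCEPT_RADIUS

# §-free defaults of the labelling stage
STATIONARY_RANGE = 0.010  # m: per-axis range of a stationary marker
STATIONARY_FRACTION = 0.60  # fraction of frames a stationary marker must occupy
LURE_HEIGHT = 0.150  # m above the floor plane
TEMPLATE_TOL = 0.005  # m tolerance on template pairwise distances
CLEAN_WINDOW_S = 0.05  # sliding-mean window
CLEAN_THRESHOLDS = (0.500, 0.075)  # m: extreme then moderate outlier passes
BIRD_SPLINE_TOL = 0.03  # m, root-sum-of-squares residual
LURE_SPLINE_TOL = 0.01  # m
MIN_RECONSTRUCTION = 0.5  # back-template visibility fraction required


class EmptyCloudError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class FlightRejected(Exception):
    """A flight failed an inclusion filter; .reason says which."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class MarkerCloud:
    """Per-frame sets of unlabelled 3D marker positions at the capture rate."""

    times: np.ndarray
    frames: list[np.ndarray]  # each (n_i, 3), metres
    true_labels: list[np.ndarray] | None = None  # ground truth (synthetic data)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class Template:
    """A rigid marker template identified by its pairwise distances."""

    name: str
    n_markers: int
    distances: np.ndarray  # sorted pairwise distances, metres
    triangles: list[np.ndarray] = field(default_factory=list)  # sorted dists of 3-subsets
    points: np.ndarray | None = None  # marker offsets in the body frame, if known

    @classmethod
    def from_points(cls, name: str, points: np.ndarray) -> "Template":
        points = np.asarray(points, dtype=float)
        m = len(points)
        dists = np.sort(
            [np.linalg.norm(points[i] - points[j]) for i, j in itertools.combinations(range(m), 2)]
        )
        if np.any(dists <= 0):
            raise ValueError("template markers must be distinct")
        triangles = []
        if m > 3:
            for combo in itertools.combinations(range(m), 3):
                tri = np.sort(
                    [np.linalg.norm(points[i] - points[j]) for i, j in itertools.combinations(combo, 2)]
                )
                triangles.append(tri)
        return cls(name, m, dists, triangles, points)


@dataclass
class LabelledCentroids:
    """Bird and lure centroid per frame; NaN rows mark missing data."""

    times: np.ndarray
    bird: np.ndarray  # (nf, 3)
    lure: np.ndarray  # (nf, 3)
    backpack_found: np.ndarray | None = None  # bool per frame

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


def _sorted_pairwise(pts: np.ndarray) -> np.ndarray:
    m = len(pts)
    return np.sort(
        [np.linalg.norm(pts[i] - pts[j]) for i, j in itertools.combinations(range(m), 2)]
    )


def _stationary_assignments(cloud: MarkerCloud, range_m: float, fraction: float):
    """Greedy clustering of points into 10 mm boxes persisting across frames.

    Returns a per-frame boolean array marking points that belong to a
    cluster occupied in at least ``fraction`` of all frames.
    """
    q = max(range_m, 1e-6)
    clusters: list[list[float]] = []  # [minx,miny,minz,maxx,maxy,maxz,count]
    cell_index: dict[tuple[int, int, int], list[int]] = {}
    member: list[list[tuple[int, int]]] = []  # cluster -> [(frame, point)]

    for fi, pts in enumerate(cloud.frames):
        for pj in range(len(pts)):
            p = pts[pj]
            key = (math.floor(p[0] / q), math.floor(p[1] / q), math.floor(p[2] / q))
            found = -1
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for ci in cell_index.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                            c = clusters[ci]
                            if (
                                max(c[3], p[0]) - min(c[0], p[0]) <= range_m
                                and max(c[4], p[1]) - min(c[1], p[1]) <= range_m
                                and max(c[5], p[2]) - min(c[2], p[2]) <= range_m
                            ):
                                found = ci
                                break
                        if found >= 0:
                            break
                    if found >= 0:
                        break
                if found >= 0:
                    break
            if found >= 0:
                c = clusters[found]
                c[0] = min(c[0], p[0])
                c[1] = min(c[1], p[1])
                c[2] = min(c[2], p[2])
                c[3] = max(c[3], p[0])
                c[4] = max(c[4], p[1])
                c[5] = max(c[5], p[2])
                c[6] += 1
                member[found].append((fi, pj))
            else:
                ci = len(clusters)
                clusters.append([p[0], p[1], p[2], p[0], p[1], p[2], 1])
                cell_index.setdefault(key, []).append(ci)
                member.append([(fi, pj)])

    need = fraction * cloud.n_frames
    flags = [np.zeros(len(pts), dtype=bool) for pts in cloud.frames]
    for ci, c in enumerate(clusters):
        if c[6] >= need:
            for fi, pj in member[ci]:
                flags[fi][pj] = True
    return flags


def _match_subset(
    cand_idx: np.ndarray, pts: np.ndarray, template: Template, tol: float
) -> tuple[np.ndarray | None, bool]:
    """Find the marker subset matching a template's pairwise distances.

    Tries full-size subsets first, then (for templates larger than three
    markers) 3-subsets against the template's sub-triangles, so a template
    with one occluded marker can still be reconstructed. Returns
    (matched indices, ambiguous): ambiguity (several distinct matches) is
    treated conservatively by the caller as a missing frame.
    """
    sizes = [template.n_markers] + ([3] if template.n_markers > 3 else [])
    for size in sizes:
        if len(cand_idx) < size:
            continue
        matches = []
        for combo in itertools.combinations(range(len(cand_idx)), size):
            sub = pts[list(combo)]
            d = _sorted_pairwise(sub)
            if size == template.n_markers:
                ok = np.all(np.abs(d - template.distances) <= tol)
            else:
                ok = any(np.all(np.abs(d - tri) <= tol) for tri in template.triangles)
            if ok:
                matches.append(np.asarray(combo))
        if len(matches) == 1:
            return cand_idx[matches[0]], False
        if len(matches) > 1:
            return None, True
    return None, False


def label_markers(
    cloud: MarkerCloud,
    templates: list[Template],
    floor_z: float = 0.0,
    stationary_range: float = STATIONARY_RANGE,
    stationary_fraction: float = STATIONARY_FRACTION,
    lure_height: float = LURE_HEIGHT,
    template_tol: float = TEMPLATE_TOL,
) -> list[np.ndarray]:
    """Classify every marker in every frame.

    Labels are 'stationary', 'lure', a template name (e.g. 'backpack',
    'tailmount'), or 'unassigned'. Stationary markers are points confined to
    the same ``stationary_range`` box in at least ``stationary_fraction`` of
    the recording's frames; of the rest, points within ``lure_height`` of
    the floor plane are lure markers and the remainder are bird markers,
    labelled by matching within-frame pairwise distances against the rigid
    templates (tolerance ``template_tol``).
    """
    if cloud.n_frames == 0:
        raise EmptyCloudError("marker cloud contains no frames")
    stationary = _stationary_assignments(cloud, stationary_range, stationary_fraction)
    labels: list[np.ndarray] = []
    for fi, pts in enumerate(cloud.frames):
        lab = np.full(len(pts), "unassigned", dtype="<U16")
        lab[stationary[fi]] = "stationary"
        moving = ~stationary[fi]
        near_floor = moving & (pts[:, 2] - floor_z <= lure_height)
        lab[near_floor] = "lure"
        bird_idx = np.flatnonzero(moving & ~near_floor)
        for template in templates:
            free = bird_idx[lab[bird_idx] == "unassigned"]
            matched, ambiguous = _match_subset(free, pts[free], template, template_tol)
            if matched is not None:
                lab[matched] = template.name
        labels.append(lab)
    return labels


def _correspondence(pts: np.ndarray, offsets: np.ndarray, tol: float, min_size: int = 3):
    """Best rigid-consistent assignment of measured points to template offsets.

    Backtracking search: each measured point is matched to an unused
    template marker or skipped, requiring every pairwise distance among the
    assigned points to agree with the template within ``tol`` (rigidity is
    checked purely through distances, so the assignment is pose-free).
    Returns (point_indices, offset_indices) of the largest consistent
    assignment with at least ``min_size`` pairs, else None.
    """
    n_p, n_t = len(pts), len(offsets)
    if n_p == 0 or n_t == 0:
        return None
    dp = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    dt = np.linalg.norm(offsets[:, None] - offsets[None, :], axis=2)
    best: list[tuple[int, int]] = []

    def recurse(i, assigned, used):
        nonlocal best
        if len(assigned) + (n_p - i) <= len(best):
            return  # cannot beat the incumbent
        if i == n_p:
            if len(assigned) > len(best):
                best = list(assigned)
            return
        for j in range(n_t):
            if j in used:
                continue
            if all(abs(dp[i, a] - dt[j, b]) <= tol for a, b in assigned):
                assigned.append((i, j))
                used.add(j)
                recurse(i + 1, assigned, used)
                assigned.pop()
                used.discard(j)
        recurse(i + 1, assigned, used)  # skip point i (occluded elsewhere / spike)

    recurse(0, [], set())
    if len(best) < min_size:
        return None
    pi = np.array([a for a, _ in best])
    ti = np.array([b for _, b in best])
    return pi, ti


def _rigid_reference(pts: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Body-frame origin implied by matched markers (planar Kabsch fit).

    Estimates the yaw rotation and translation mapping the body-frame
    offsets onto the measured points in the horizontal plane (flight is
    treated as roll- and pitch-free) and returns the position of the body
    origin; z is the mean marker height correction.
    """
    p_xy = pts[:, :2]
    o_xy = offsets[:, :2]
    pbar = p_xy.mean(axis=0)
    obar = o_xy.mean(axis=0)
    pc = p_xy - pbar
    oc = o_xy - obar
    sxx = float(np.sum(oc * pc))
    sxy = float(np.sum(oc[:, 0] * pc[:, 1] - oc[:, 1] * pc[:, 0]))
    th = math.atan2(sxy, sxx)
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, -s], [s, c]])
    t = pbar - rot @ obar
    z = float(np.mean(pts[:, 2] - offsets[:, 2]))
    return np.array([t[0], t[1], z])


def compute_centroids(
    cloud: MarkerCloud,
    labels: list[np.ndarray],
    templates: list[Template] | None = None,
    lure_template: Template | None = None,
    min_markers: int = 3,
    combine_tail: bool = True,
    template_tol: float = TEMPLATE_TOL,
) -> LabelledCentroids:
    """Bird and lure reference positions from labelled markers.

    When templates with body-frame offsets are supplied (the default
    pipeline), the bird position is the rigid-body registration of the
    identified backpack and tail-mount markers against their combined
    template, which keeps the reference point stable under partial
    occlusion; the lure position is registered likewise when a lure
    template is given. Without offsets the positions fall back to the plain
    centroid of the identified markers (backpack plus tail mount, backpack
    alone when the tail mount is missing). A position is reported only when
    at least ``min_markers`` backpack (resp. lure) markers contribute.
    """
    by_name = {t.name: t for t in (templates or []) if t.points is not None}
    body_offsets = None
    if "backpack" in by_name:
        parts = [by_name["backpack"].points]
        n_backpack = len(parts[0])
        if combine_tail and "tailmount" in by_name:
            parts.append(by_name["tailmount"].points)
        body_offsets = np.vstack(parts)

    nf = cloud.n_frames
    bird = np.full((nf, 3), np.nan)
    lure = np.full((nf, 3), np.nan)
    backpack_found = np.zeros(nf, dtype=bool)
    for fi, (pts, lab) in enumerate(zip(cloud.frames, labels)):
        bp = pts[lab == "backpack"]
        tm = pts[lab == "tailmount"]
        if body_offsets is not None:
            body_pts = np.vstack([bp, tm]) if (combine_tail and len(tm)) else bp
            match = _correspondence(body_pts, body_offsets, template_tol, min_markers)
            if match is not None:
                pi, ti = match
                if np.sum(ti < n_backpack) >= min_markers:
                    backpack_found[fi] = True
                    bird[fi] = _rigid_reference(body_pts[pi], body_offsets[ti])
        elif len(bp) >= min_markers:
            backpack_found[fi] = True
            parts = [bp]
            if combine_tail and len(tm) >= min_markers:
                parts.append(tm)
            bird[fi] = np.mean(np.vstack(parts), axis=0)

        lu = pts[lab == "lure"]
        if lure_template is not None and lure_template.points is not None:
            match = _correspondence(lu, lure_template.points, template_tol, min_markers)
            if match is not None:
                pi, ti = match
                lure[fi] = _rigid_reference(lu[pi], lure_template.points[ti])
        elif len(lu) >= min_markers:
            lure[fi] = np.mean(lu, axis=0)
    return LabelledCentroids(cloud.times.copy(), bird, lure, backpack_found)


def _sliding_mean(xyz: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean over non-missing frames, per axis."""
    nf = len(xyz)
    finite = np.isfinite(xyz[:, 0])
    filled = np.where(finite[:, None], xyz, 0.0)
    half = window // 2
    kernel = np.ones(window)
    counts = np.convolve(finite.astype(float), kernel, mode="same")
    out = np.full_like(xyz, np.nan)
    with np.errstate(invalid="ignore"):
        for ax in range(xyz.shape[1]):
            s = np.convolve(filled[:, ax], kernel, mode="same")
            out[:, ax] = np.where(counts > 0, s / np.maximum(counts, 1), np.nan)
    return out


def _clean_series(times: np.ndarray, xyz: np.ndarray, window_s: float, thresholds) -> np.ndarray:
    rate = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 200.0
    window = int(round(window_s * rate))
    window = max(window | 1, 3)  # centered, odd
    out = xyz.copy()
    half = window // 2
    testable = np.zeros(len(out), dtype=bool)
    testable[half : len(out) - half] = True  # boundary frames keep a one-sided
    # window whose mean lags a fast track by design, so they are not tested
    for thr in thresholds:
        mean = _sliding_mean(out, window)
        dist = np.linalg.norm(out - mean, axis=1)
        with np.errstate(invalid="ignore"):
            bad = testable & (dist > thr)
        out[bad] = np.nan
    return out


def clean_trajectory(
    centroids: LabelledCentroids,
    window_s: float = CLEAN_WINDOW_S,
    thresholds: tuple[float, float] = CLEAN_THRESHOLDS,
) -> LabelledCentroids:
    """Two-pass sliding-window outlier elimination on the centroid tracks.

    Pass one removes extreme outliers (default > 500 mm from the 0.05 s
    window mean); the window means are then recomputed and pass two removes
    moderate outliers (default > 75 mm). Removed points become missing.
    """
    return LabelledCentroids(
        centroids.times.copy(),
        _clean_series(centroids.times, centroids.bird, window_s, thresholds),
        _clean_series(centroids.times, centroids.lure, window_s, thresholds),
        None if centroids.backpack_found is None else centroids.backpack_found.copy(),
    )


@dataclass
class SmoothedTrack:
    """Quintic smoothing-spline representation of a centroid track."""

    t0: float
    t1: float
    splines: list[UnivariateSpline]
    times: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    frame_times: np.ndarray
    frame_values: np.ndarray  # raw frames (NaN where missing), cropped
    tolerance: float

    def evaluate(self, t: np.ndarray, der: int = 0) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack([s.derivative(der)(t) if der else s(t) for s in self.splines], axis=-1)


def smooth_and_differentiate(
    times: np.ndarray,
    values: np.ndarray,
    tolerance: float,
    out_rate: float = 20000.0,
) -> SmoothedTrack:
    """Fill gaps, fit a quintic smoothing spline, differentiate analytically.

    Interior gaps are filled by cubic interpolation across the observed
    frames; the degree-5 smoothing spline is then the smoothest spline whose
    root-sum-of-squares residual over the frames does not exceed
    ``tolerance`` (the tolerance is split evenly across axes). Position,
    velocity and acceleration are evaluated on a uniform grid at
    ``out_rate`` (default 20 kHz).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    finite = np.isfinite(values).all(axis=1)
    if finite.sum() < 6:
        raise InsufficientDataError("need at least six observed frames for a quintic spline")
    first, last = np.flatnonzero(finite)[[0, -1]]
    t = times[first : last + 1]
    v = values[first : last + 1].copy()
    raw = v.copy()
    fin = finite[first : last + 1]
    if not fin.all():
        cs = CubicSpline(t[fin], v[fin], axis=0)
        v[~fin] = cs(t[~fin])

    dims = v.shape[1]
    s = tolerance**2 / dims
    splines = [UnivariateSpline(t, v[:, ax], k=5, s=s) for ax in range(dims)]

    step = 1.0 / out_rate
    n = int(math.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    grid = t[0] + np.arange(n) * step
    pos = np.stack([sp(grid) for sp in splines], axis=-1)
    vel = np.stack([sp.derivative(1)(grid) for sp in splines], axis=-1)
    acc = np.stack([sp.derivative(2)(grid) for sp in splines], axis=-1)
    return SmoothedTrack(float(t[0]), float(t[-1]), splines, grid, pos, vel, acc, t, raw, tolerance)


def qc_and_crop(
    bird: SmoothedTrack,
    lure: SmoothedTrack,
    reconstruction_fraction: float,
    flight_id: str = "flight",
    out_dt: float = 5e-5,
    intercept_radius: float = INTERCEPT_RADIUS,
    min_reconstruction: float = MIN_RECONSTRUCTION,
    meta: dict | None = None,
) -> Flight:
    """Apply the inclusion filters and assemble a Flight.

    Rejects (raises FlightRejected) when the back template was reconstructed
    in no more than ``min_reconstruction`` of the frames, when bird and lure
    are never simultaneously visible, or when the hawk never comes within
    the intercept radius of the lure. Otherwise the tracks are cropped to
    the first mutually visible frame and truncated at the intercept time
    (first approach within the radius), and times are shifted to start at 0.
    """
    if reconstruction_fraction <= min_reconstruction:
        raise FlightRejected(
            f"back template reconstructed in {reconstruction_fraction:.0%} of frames "
            f"(need > {min_reconstruction:.0%})"
        )
    t0 = max(bird.t0, lure.t0)
    t1 = min(bird.t1, lure.t1)
    if t1 <= t0:
        raise FlightRejected("bird and lure are never simultaneously visible")

    # intercept criterion evaluated on the measured frames (both visible)
    common = np.intersect1d(bird.frame_times, lure.frame_times)
    common = common[(common >= t0) & (common <= t1)]
    bsel = np.isin(bird.frame_times, common)
    lsel = np.isin(lure.frame_times, common)
    bxy = bird.frame_values[bsel, :2]
    lxy = lure.frame_values[lsel, :2]
    fdist = np.hypot(bxy[:, 0] - lxy[:, 0], bxy[:, 1] - lxy[:, 1])
    ok = np.isfinite(fdist)
    if not ok.any():
        raise FlightRejected("bird and lure are never simultaneously visible")
    hit = np.flatnonzero(ok & (fdist <= intercept_radius))
    if len(hit) == 0:
        raise FlightRejected(
            f"no intercept: minimum approach {np.nanmin(fdist) * 1000:.0f} mm exceeds "
            f"{intercept_radius * 1000:.0f} mm"
        )
    t_int = float(common[hit[0]])

    n = int(math.floor((t_int - t0) / out_dt + 1e-9)) + 1
    grid = t0 + np.arange(n) * out_dt
    bird_pos = bird.evaluate(grid)
    lure_pos = lure.evaluate(grid)
    bird_vel = bird.evaluate(grid, der=1)
    lure_vel = lure.evaluate(grid, der=1)

    in_win = (bird.frame_times >= t0 - 1e-9) & (bird.frame_times <= grid[-1] + 1e-9)
    f_times = bird.frame_times[in_win] - t0
    f_bird = bird.frame_values[in_win]
    lure_sel = (lure.frame_times >= t0 - 1e-9) & (lure.frame_times <= grid[-1] + 1e-9)
    f_lure = lure.frame_values[lure_sel]
    if len(f_lure) != len(f_times):  # tracks observed on different frame sets
        f_lure = None

    m = meta.copy() if meta else {}
    m.setdefault("time_offset_s", float(t0))
    return Flight(
        flight_id=flight_id,
        dt=out_dt,
        times=grid - t0,
        hawk_pos=bird_pos[:, :2],
        hawk_vel=bird_vel[:, :2],
        hawk_speed=np.hypot(bird_vel[:, 0], bird_vel[:, 1]),
        lure_pos=lure_pos[:, :2],
        lure_vel=lure_vel[:, :2],
        frame_times=f_times,
        hawk_frames=f_bird[:, :2],
        lure_frames=None if f_lure is None else f_lure[:, :2],
        hawk_frames_z=f_bird[:, 2] if f_bird.shape[1] > 2 else None,
        lure_frames_z=None if f_lure is None or f_lure.shape[1] < 3 else f_lure[:, 2],
        intercept_time=float(grid[-1] - t0),
        meta=m,
    )


def preprocess_cloud(
    cloud: MarkerCloud,
    templates: list[Template],
    flight_id: str = "flight",
    floor_z: float = 0.0,
    bird_tolerance: float = BIRD_SPLINE_TOL,
    lure_tolerance: float = LURE_SPLINE_TOL,
    out_dt: float = 5e-5,
    combine_tail: bool = True,
    lure_template: Template | None = None,
) -> Flight:
    """Full preprocessing chain: marker cloud to a clean, smoothed Flight."""
    labels = label_markers(cloud, templates, floor_z=floor_z)
    cents = compute_centroids(
        cloud, labels, templates=templates, lure_template=lure_template,
        combine_tail=combine_tail,
    )
    cents = clean_trajectory(cents)
    bird = smooth_and_differentiate(
        cents.times, cents.bird, bird_tolerance, out_rate=1.0 / out_dt
    )
    lure = smooth_and_differentiate(
        cents.times, cents.lure, lure_tolerance, out_rate=1.0 / out_dt
    )
    frac = float(np.mean(cents.backpack_found)) if cents.backpack_found is not None else 1.0
    return qc_and_crop(
        bird, lure, frac, flight_id=flight_id, out_dt=out_dt
    )
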