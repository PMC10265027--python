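"""Plain-text file formats: flight tables, marker clouds, run manifests.

Flights are stored as CSV with a commented header of ``# key: value``
metadata lines followed by one row per 200 Hz frame
(time_s, hawk_x_m, hawk_y_m, hawk_z_m, lure_x_m, lure_y_m, lure_z_m);
missing values are empty fields. Numeric fields round-trip at full float
precision. Marker clouds are long-format CSV
(frame, time_s, x_m, y_m, z_m[, label]).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .flight import Flight
from .preprocess import MarkerCloud, smooth_and_differentiate

FLIGHT_MAGIC = "# pursuitfit flight v1"
FLIGHT_COLUMNS = "time_s,hawk_x_m,hawk_y_m,hawk_z_m,lure_x_m,lure_y_m,lure_z_m"


class FlightParseError(ValueError):
    pass


@dataclass
class FlightFrames:
    """The on-disk representation of a flight: 200 Hz frames plus metadata."""

    times: np.ndarray
    hawk: np.ndarray  # (nf, 3), NaN where missing
    lure: np.ndarray  # (nf, 3)
    meta: dict = field(default_factory=dict)


def _fmt(x: float) -> str:
    return "" if not math.isfinite(x) else repr(float(x))


def write_flight(flight: Flight, path: str | Path) -> None:
    """Serialise a flight's measurement frames and metadata to CSV."""
    path = Path(path)
    lines = [FLIGHT_MAGIC]
    meta = {
        "flight_id": flight.flight_id,
        "frame_rate_hz": flight.frame_rate,
        "intercept_time_s": flight.intercept_time,
        "units": "m,s",
    }
    for k, v in flight.meta.items():
        if isinstance(v, (str, int, float, bool)):
            meta[k] = v
    for k, v in meta.items():
        lines.append(f"# {k}: {json.dumps(v) if isinstance(v, str) else v}")
    lines.append(FLIGHT_COLUMNS)
    hz = flight.hawk_frames_z
    lz = flight.lure_frames_z
    lure = flight.lure_frames
    for i, t in enumerate(flight.frame_times):
        hx, hy = flight.hawk_frames[i]
        h3 = hz[i] if hz is not None else math.nan
        if lure is not None:
            lx, ly = lure[i]
        else:
            lx = ly = math.nan
        l3 = lz[i] if lz is not None else math.nan
        lines.append(
            ",".join([_fmt(t), _fmt(hx), _fmt(hy), _fmt(h3), _fmt(lx), _fmt(ly), _fmt(l3)])
        )
    path.write_text("\n".join(lines) + "\n")


def read_flight_frames(path: str | Path) -> FlightFrames:
    """Parse a flight CSV back into frames; inverse of write_flight."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# pursuitfit flight"):
        raise FlightParseError(f"{path}: not a flight file (bad magic line)")
    meta: dict = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if ":" in body:
            k, v = body.split(":", 1)
            v = v.strip()
            try:
                meta[k.strip()] = json.loads(v)
            except json.JSONDecodeError:
                meta[k.strip()] = v
        i += 1
    if i >= len(lines) or lines[i] != FLIGHT_COLUMNS:
        raise FlightParseError(f"{path}: missing column header at line {i + 1}")
    times, hawk, lure = [], [], []
    prev_t = -math.inf
    for row_no, line in enumerate(lines[i + 1 :], start=1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise FlightParseError(f"{path}: row {row_no}: expected 7 fields")
        vals = [float(p) if p != "" else math.nan for p in parts]
        t = vals[0]
        if not t > prev_t:
            raise FlightParseError(f"{path}: row {row_no}: time not strictly increasing")
        prev_t = t
        times.append(t)
        hawk.append(vals[1:4])
        lure.append(vals[4:7])
    return FlightFrames(np.asarray(times), np.asarray(hawk), np.asarray(lure), meta)


def read_flight(
    path: str | Path,
    out_dt: float = 5e-5,
    bird_tolerance: float = 0.03,
    lure_tolerance: float = 0.01,
) -> Flight:
    """Load a flight file and rebuild the dense tracks by spline smoothing.

    The stored 200 Hz frames are smoothed with the standard quintic-spline
    tolerances and evaluated on a dense grid at ``out_dt``; the frames
    themselves are preserved verbatim on the returned Flight.
    """
    ff = read_flight_frames(path)
    # planar flights may carry no z column at all; smooth only observed axes
    hawk_obs = ff.hawk if np.isfinite(ff.hawk[:, 2]).any() else ff.hawk[:, :2]
    lure_obs = ff.lure if np.isfinite(ff.lure[:, 2]).any() else ff.lure[:, :2]
    bird = smooth_and_differentiate(ff.times, hawk_obs, bird_tolerance, out_rate=1.0 / out_dt)
    lure = smooth_and_differentiate(ff.times, lure_obs, lure_tolerance, out_rate=1.0 / out_dt)
    t0 = max(bird.t0, lure.t0)
    t1 = min(bird.t1, lure.t1)
    n = int(math.floor((t1 - t0) / out_dt + 1e-9)) + 1
    grid = t0 + np.arange(n) * out_dt
    bp = bird.evaluate(grid)
    bv = bird.evaluate(grid, der=1)
    lp = lure.evaluate(grid)
    lv = lure.evaluate(grid, der=1)
    sel = (ff.times >= t0 - 1e-9) & (ff.times <= t1 + 1e-9)
    meta = dict(ff.meta)
    intercept = float(meta.pop("intercept_time_s", grid[-1] - t0))
    return Flight(
        flight_id=str(meta.pop("flight_id", path.stem if isinstance(path, Path) else "flight")),
        dt=out_dt,
        times=grid - t0,
        hawk_pos=bp[:, :2],
        hawk_vel=bv[:, :2],
        hawk_speed=np.hypot(bv[:, 0], bv[:, 1]),
        lure_pos=lp[:, :2],
        lure_vel=lv[:, :2],
        frame_times=ff.times[sel] - t0,
        hawk_frames=ff.hawk[sel, :2],
        lure_frames=ff.lure[sel, :2],
        hawk_frames_z=ff.hawk[sel, 2],
        lure_frames_z=ff.lure[sel, 2],
        intercept_time=intercept,
        meta=meta,
    )


def write_marker_cloud(cloud: MarkerCloud, path: str | Path) -> None:
    path = Path(path)
    lines = ["frame,time_s,x_m,y_m,z_m,label"]
    for fi, pts in enumerate(cloud.frames):
        labs = cloud.true_labels[fi] if cloud.true_labels is not None else [""] * len(pts)
        for p, lab in zip(pts, labs):
            lines.append(
                f"{fi},{_fmt(cloud.times[fi])},{_fmt(p[0])},{_fmt(p[1])},{_fmt(p[2])},{lab}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_marker_cloud(path: str | Path) -> MarkerCloud:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("frame,time_s"):
        raise FlightParseError(f"{path}: not a marker-cloud file")
    has_label = lines[0].split(",")[-1] == "label"
    frames: dict[int, list] = {}
    labels: dict[int, list] = {}
    times: dict[int, float] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split(",")
        fi = int(parts[0])
        times[fi] = float(parts[1])
        frames.setdefault(fi, []).append([float(parts[2]), float(parts[3]), float(parts[4])])
        if has_label:
            labels.setdefault(fi, []).append(parts[5])
    order = sorted(frames)
    t = np.array([times[fi] for fi in order])
    fr = [np.asarray(frames[fi]) for fi in order]
    lab = [np.asarray(labels[fi], dtype="<U16") for fi in order] if has_label else None
    return MarkerCloud(t, fr, lab)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_manifest(path: str | Path, **entries) -> None:
    payload = dict(entries)
    payload["config_hash"] = config_hash(entries)
    Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")
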