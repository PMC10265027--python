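"""The Flight container: paired pursuer/target tracks on a common time base.

A Flight is the unit the whole pipeline operates on. It carries two
representations of the chase:

* dense tracks sampled at the integration step ``dt`` (positions and
  velocities for hawk and lure, plus the hawk's measured speed profile fed
  to the speed-matched simulator), and
* the raw measurement frames at the motion-capture rate (200 Hz), which are
  what the RMS fitting error is evaluated against.

Times are measured from the onset of target motion (t = 0) and run to the
intercept time, defined as the first approach within the intercept radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FRAME_RATE = 200.0
INTERCEPT_RADIUS = 0.030  # m


@dataclass
class Flight:
    flight_id: str
    dt: float
    times: np.ndarray  # dense grid, times[0] == 0
    hawk_pos: np.ndarray  # (M, 2)
    hawk_vel: np.ndarray  # (M, 2)
    hawk_speed: np.ndarray  # (M,) measured speed profile for speed matching
    lure_pos: np.ndarray  # (M, 2)
    lure_vel: np.ndarray  # (M, 2)
    frame_times: np.ndarray  # (nf,)
    hawk_frames: np.ndarray  # (nf, 2), NaN where missing
    lure_frames: np.ndarray | None = None
    hawk_frames_z: np.ndarray | None = None
    lure_frames_z: np.ndarray | None = None
    intercept_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and abs(self.times[0]) > 1e-12:
            raise ValueError("dense flight times must start at t = 0")
        m = len(self.times)
        for name in ("hawk_pos", "hawk_vel", "lure_pos", "lure_vel"):
            arr = np.ascontiguousarray(getattr(self, name), dtype=float)
            if arr.shape != (m, 2):
                raise ValueError(f"{name} must have shape ({m}, 2)")
            setattr(self, name, arr)
        self.hawk_speed = np.ascontiguousarray(self.hawk_speed, dtype=float)
        if self.hawk_speed.shape != (m,):
            raise ValueError("hawk_speed must match the dense grid")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.hawk_frames = np.asarray(self.hawk_frames, dtype=float)

    @property
    def frame_rate(self) -> float:
        if len(self.frame_times) < 2:
            return FRAME_RATE
        return 1.0 / float(np.median(np.diff(self.frame_times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def frame_dense_indices(self) -> np.ndarray:
        """Dense-grid index of each measurement frame."""
        idx = np.round(self.frame_times / self.dt).astype(np.int64)
        if np.any(np.abs(idx * self.dt - self.frame_times) > 1e-9):
            raise ValueError("frame times do not lie on the dense grid")
        return idx
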