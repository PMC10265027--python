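"""Guidance-parameter estimation, per flight and globally across flights.

Per-flight fitting minimises the RMS position error between the simulated
and measured hawk trajectories: for each delay on the tau grid, a
Nelder-Mead search (multi-start, gains unconstrained in sign) optimises the
continuous gain(s), and the best (tau, gains) pair is returned.

Global fitting evaluates the error exhaustively on a parameter grid
(defaults: N on [0, 1.5] step 0.1, K on [0, 5] /s step 0.2, tau on
[0, 0.15] s step 0.005) for every flight, then minimises the cell-wise
median error across flights. Because PP and the pure PN laws are the N=0 /
K=0 special cases of the mixed law, their global optima are sub-grid slices
of the mixed-law grid.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from . import _engine
from .flight import Flight
from .guidance import GuidanceLaw, GuidanceParams, SimConfig, SimTrajectory

N_GRID_DEFAULT = np.round(np.arange(0.0, 1.5 + 1e-9, 0.1), 10)
K_GRID_DEFAULT = np.round(np.arange(0.0, 5.0 + 1e-9, 0.2), 10)
TAU_GRID_DEFAULT = np.round(np.arange(0.0, 0.15 + 1e-9, 0.005), 10)

GAIN_STARTS_N = (0.0, 0.5, 1.0)
GAIN_STARTS_K = (0.0, 1.0, 3.0)


@dataclass
class FitResult:
    """Best-fitting parameters for a single flight (hat notation)."""

    flight_id: str
    law: GuidanceLaw
    n_hat: float
    k_hat: float
    tau_hat: float
    eps_hat: float  # RMS error, metres

    @property
    def params(self) -> GuidanceParams:
        return GuidanceParams(self.law, N=self.n_hat, K=self.k_hat, tau=self.tau_hat)


@dataclass
class GlobalFitResult:
    """Globally fitted parameters across flights (breve/tilde notation)."""

    law: GuidanceLaw
    n_breve: float
    k_breve: float
    tau_breve: float
    eps_tilde: float  # median RMS error across flights, metres
    index: tuple[int, int, int] = (0, 0, 0)  # (iN, iK, iTau) in the source grid

    @property
    def params(self) -> GuidanceParams:
        return GuidanceParams(self.law, N=self.n_breve, K=self.k_breve, tau=self.tau_breve)


def rms_error(sim: SimTrajectory, frame_times: np.ndarray, frame_pos: np.ndarray) -> float:
    """Root-mean-square distance between simulated and measured positions.

    Evaluated at the measurement frames (the 200 Hz samples), which must be
    covered by the simulated trajectory; frames with missing (NaN) measured
    positions are skipped.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    frame_pos = np.asarray(frame_pos, dtype=float)
    if len(frame_times) == 0:
        raise ValueError("no measurement frames to evaluate")
    dt = sim.times[1] - sim.times[0]
    idx = np.round((frame_times - sim.times[0]) / dt).astype(np.int64)
    if np.any(idx < 0) or np.any(idx >= len(sim.times)):
        raise ValueError("simulated trajectory does not cover all evaluation frames")
    ok = np.isfinite(frame_pos).all(axis=1)
    if not ok.any():
        raise ValueError("all evaluation frames are missing")
    d = sim.positions[idx[ok]] - frame_pos[ok]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _engine_args(flight: Flight, cfg: SimConfig, background: bool):
    """Dense arrays, pre-start feedback and evaluation frames for a flight."""
    i0 = int(round(cfg.start_time / flight.dt))
    if i0 < 0 or i0 >= len(flight.times) - 1:
        raise ValueError("flight does not cover the simulation window")
    # simulate and score on [t_start, intercept]; recordings may extend a
    # little past first contact but the chase ends there
    i_end = min(len(flight.times) - 1, int(round(flight.intercept_time / flight.dt)))
    if i_end <= i0:
        raise ValueError("flight intercept occurs before the simulation start")
    md, ml = _engine.measured_delta_los(
        flight.lure_pos, flight.lure_vel, flight.hawk_pos, flight.hawk_vel, i0, background
    )
    fidx = flight.frame_dense_indices()
    ok = (
        (fidx >= i0)
        & (fidx <= i_end)
        & np.isfinite(flight.hawk_frames).all(axis=1)
    )
    frame_k = np.ascontiguousarray(fidx[ok] - i0, dtype=np.int64)
    frame_pos = np.ascontiguousarray(flight.hawk_frames[ok], dtype=float)
    if len(frame_k) == 0:
        raise ValueError("no usable evaluation frames on [t_start, intercept]")
    r0 = flight.hawk_pos[i0]
    v0 = flight.hawk_vel[i0]
    return (
        flight.lure_pos,
        flight.lure_vel,
        flight.hawk_speed,
        md,
        ml,
        i0,
        i_end,
        frame_k,
        frame_pos,
        float(r0[0]),
        float(r0[1]),
        float(v0[0]),
        float(v0[1]),
    )


def _rms_for_gains(args, d: int, dt: float, Ns: np.ndarray, Ks: np.ndarray, background: bool):
    (tpos, tvel, speed, md, ml, i0, i_end, frame_k, frame_pos, r0x, r0y, v0x, v0y) = args
    return _engine.rms_batch(
        tpos,
        tvel,
        speed,
        md,
        ml,
        i0,
        i_end,
        d,
        dt,
        np.ascontiguousarray(Ns, dtype=float),
        np.ascontiguousarray(Ks, dtype=float),
        background,
        frame_k,
        frame_pos,
        r0x,
        r0y,
        v0x,
        v0y,
    )


def error_for_params(flight: Flight, params: GuidanceParams, cfg: SimConfig | None = None) -> float:
    """RMS error of one parameter set on one flight."""
    cfg = cfg or SimConfig(dt=flight.dt)
    args = _engine_args(flight, cfg, params.law.uses_background)
    d = cfg.delay_steps(params.tau)
    return float(
        _rms_for_gains(
            args, d, cfg.dt, np.array([params.n_eff]), np.array([params.k_eff]),
            params.law.uses_background,
        )[0]
    )


def fit_flight(
    flight: Flight,
    law: GuidanceLaw,
    cfg: SimConfig | None = None,
    tau_grid: np.ndarray | None = None,
    gain_starts: list[tuple[float, ...]] | None = None,
    xatol: float = 1e-4,
    fatol: float = 1e-10,
    maxiter: int = 400,
) -> FitResult:
    """Fit guidance parameters to one flight by RMS-error minimisation.

    For each delay on ``tau_grid`` the continuous gain(s) are optimised by a
    multi-start Nelder-Mead simplex search (unconstrained in sign); the
    delay/gain combination with the smallest error wins. Besides the fixed
    gain starts, the best cell of a coarse gain grid is used as a start at
    each delay, which keeps the search robust on flights whose error surface
    has a narrow global basin.
    """
    cfg = cfg or SimConfig(dt=flight.dt)
    tau_grid = TAU_GRID_DEFAULT if tau_grid is None else np.asarray(tau_grid, float)
    background = law.uses_background
    args = _engine_args(flight, cfg, background)

    if gain_starts is None:
        if law.n_gains == 2:
            gain_starts = list(itertools.product(GAIN_STARTS_N, GAIN_STARTS_K))
        elif law.uses_n:
            gain_starts = [(s,) for s in GAIN_STARTS_N]
        else:
            gain_starts = [(s,) for s in GAIN_STARTS_K]

    def unpack(x):
        if law.n_gains == 2:
            return x[0], x[1]
        if law.uses_n:
            return x[0], 0.0
        return 0.0, x[0]

    scan_n = N_GRID_DEFAULT if law.uses_n else np.array([0.0])
    scan_k = K_GRID_DEFAULT if law.uses_k else np.array([0.0])
    NN, KK = np.meshgrid(scan_n, scan_k, indexing="ij")
    scan_N = np.ascontiguousarray(NN.ravel())
    scan_K = np.ascontiguousarray(KK.ravel())

    best = None
    for tau in tau_grid:
        d = cfg.delay_steps(float(tau))

        def objective(x):
            n, k = unpack(x)
            return float(
                _rms_for_gains(args, d, cfg.dt, np.array([n]), np.array([k]), background)[0]
            )

        scan = _rms_for_gains(args, d, cfg.dt, scan_N, scan_K, background)
        b = int(np.argmin(scan))
        if law.n_gains == 2:
            grid_start = (float(scan_N[b]), float(scan_K[b]))
        elif law.uses_n:
            grid_start = (float(scan_N[b]),)
        else:
            grid_start = (float(scan_K[b]),)

        for start in [grid_start, *gain_starts]:
            res = minimize(
                objective,
                np.asarray(start, dtype=float),
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
                n, k = unpack(res.x)
                best = (float(res.fun), n, k, float(tau))
    if best is None:
        raise RuntimeError("all candidate simulations failed")
    eps, n, k, tau = best
    return FitResult(flight.flight_id, law, n, k, tau, eps)


@dataclass
class ErrorGrid:
    """Per-flight RMS error over the (N, K, tau) grid for one law family.

    ``values`` has shape (n_flights, len(n_axis), len(k_axis), len(tau_axis)).
    For pure PN laws the K axis is the single value 0, and for PP the N axis
    is the single value 0.
    """

    law: GuidanceLaw
    n_axis: np.ndarray
    k_axis: np.ndarray
    tau_axis: np.ndarray
    values: np.ndarray
    flight_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_flights(self) -> int:
        return self.values.shape[0]

    def flight_errors(self, index: tuple[int, int, int]) -> np.ndarray:
        """Per-flight errors at one grid cell."""
        i, j, k = index
        return self.values[:, i, j, k]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            values=self.values,
            n_axis=self.n_axis,
            k_axis=self.k_axis,
            tau_axis=self.tau_axis,
        )
        sidecar = {"law": self.law.value, "flight_ids": self.flight_ids, "meta": self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ErrorGrid":
        path = Path(path)
        with np.load(path) as z:
            values = z["values"]
            n_axis = z["n_axis"]
            k_axis = z["k_axis"]
            tau_axis = z["tau_axis"]
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            GuidanceLaw(sidecar["law"]),
            n_axis,
            k_axis,
            tau_axis,
            values,
            sidecar["flight_ids"],
            sidecar.get("meta", {}),
        )


def build_error_grid(
    flights: list[Flight],
    law: GuidanceLaw,
    cfg: SimConfig | None = None,
    n_grid: np.ndarray | None = None,
    k_grid: np.ndarray | None = None,
    tau_grid: np.ndarray | None = None,
) -> ErrorGrid:
    """Exhaustively evaluate the RMS error on the parameter grid.

    Gains that the law does not use collapse to the single value 0, so a
    PN grid is exactly the K = 0 slice of the corresponding mixed-law grid.
    A failed simulation scores +inf in its cell.
    """
    if not flights:
        raise ValueError("need at least one flight")
    cfg = cfg or SimConfig(dt=flights[0].dt)
    n_axis = np.asarray(N_GRID_DEFAULT if n_grid is None else n_grid, float)
    k_axis = np.asarray(K_GRID_DEFAULT if k_grid is None else k_grid, float)
    tau_axis = np.asarray(TAU_GRID_DEFAULT if tau_grid is None else tau_grid, float)
    if not law.uses_n:
        n_axis = np.array([0.0])
    if not law.uses_k:
        k_axis = np.array([0.0])
    background = law.uses_background

    NN, KK = np.meshgrid(n_axis, k_axis, indexing="ij")
    Ns = np.ascontiguousarray(NN.ravel())
    Ks = np.ascontiguousarray(KK.ravel())
    values = np.empty((len(flights), len(n_axis), len(k_axis), len(tau_axis)))
    for fi, flight in enumerate(flights):
        args = _engine_args(flight, cfg, background)
        for ti, tau in enumerate(tau_axis):
            d = cfg.delay_steps(float(tau))
            rms = _rms_for_gains(args, d, cfg.dt, Ns, Ks, background)
            values[fi, :, :, ti] = rms.reshape(len(n_axis), len(k_axis))
    return ErrorGrid(
        law,
        n_axis,
        k_axis,
        tau_axis,
        values,
        [f.flight_id for f in flights],
        {"dt": cfg.dt, "tau_max": cfg.tau_max},
    )


def argmin_lexicographic(
    median: np.ndarray,
    n_axis: np.ndarray,
    k_axis: np.ndarray,
    tau_axis: np.ndarray,
) -> tuple[int, int, int]:
    """Grid argmin with deterministic tie-break: smallest (tau, N, K)."""
    m = np.min(median)
    cand = np.argwhere(median == m)
    key = lambda c: (tau_axis[c[2]], n_axis[c[0]], k_axis[c[1]])
    best = min(cand, key=key)
    return int(best[0]), int(best[1]), int(best[2])


def _law_slices(grid: ErrorGrid, law: GuidanceLaw):
    """Index arrays selecting the sub-grid appropriate to a (nested) law."""
    if law is grid.law:
        return np.arange(len(grid.n_axis)), np.arange(len(grid.k_axis))
    if law is GuidanceLaw.PP and grid.law.uses_n and grid.law.uses_k:
        n_sel = np.flatnonzero(grid.n_axis == 0.0)
        if len(n_sel) == 0:
            raise ValueError("grid N axis does not contain 0; PP slice unavailable")
        return n_sel, np.arange(len(grid.k_axis))
    pnp_of = {
        GuidanceLaw.INERTIAL_PN: GuidanceLaw.INERTIAL_PNP,
        GuidanceLaw.BACKGROUND_PN: GuidanceLaw.BACKGROUND_PNP,
    }
    if law in pnp_of and grid.law is pnp_of[law]:
        k_sel = np.flatnonzero(grid.k_axis == 0.0)
        if len(k_sel) == 0:
            raise ValueError("grid K axis does not contain 0; PN slice unavailable")
        return np.arange(len(grid.n_axis)), k_sel
    raise ValueError(f"law {law.value} is not nested in a {grid.law.value} grid")


def global_fit(grid: ErrorGrid, law: GuidanceLaw | None = None) -> GlobalFitResult:
    """Minimise the cell-wise median RMS error over the (sub-)grid.

    The median over flights is taken cell by cell; ties at the minimum break
    deterministically to the lexicographically smallest (tau, N, K).
    """
    law = law or grid.law
    n_sel, k_sel = _law_slices(grid, law)
    sub = grid.values[:, n_sel[:, None], k_sel[None, :], :]
    med = np.median(sub, axis=0)
    i, j, t = argmin_lexicographic(med, grid.n_axis[n_sel], grid.k_axis[k_sel], grid.tau_axis)
    gi, gj = int(n_sel[i]), int(k_sel[j])
    return GlobalFitResult(
        law,
        float(grid.n_axis[gi]) if law.uses_n else 0.0,
        float(grid.k_axis[gj]) if law.uses_k else 0.0,
        float(grid.tau_axis[t]),
        float(med[i, j, t]),
        index=(gi, gj, int(t)),
    )
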