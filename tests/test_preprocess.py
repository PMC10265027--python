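"""Marker labelling, outlier cleaning, spline smoothing and QC filters."""

import numpy as np
import pytest

from pursuitfit.flight import FRAME_RATE
from pursuitfit.preprocess import (
    EmptyCloudError,
    FlightRejected,
    InsufficientDataError,
    LabelledCentroids,
    MarkerCloud,
    Template,
    clean_trajectory,
    compute_centroids,
    label_markers,
    qc_and_crop,
    smooth_and_differentiate,
)
from pursuitfit.synthetic import BACKPACK_OFFSETS, default_templates

DT = 1.0 / FRAME_RATE


def make_cloud(point_lists):
    times = np.arange(len(point_lists)) * DT
    frames = [np.asarray(p, dtype=float).reshape(-1, 3) for p in point_lists]
    return MarkerCloud(times, frames)


class TestLabelling:
    def test_fixed_marker_is_stationary(self):
        pt = [4.0, 2.0, 0.4]
        cloud = make_cloud([[pt]] * 40)
        labels = label_markers(cloud, default_templates())
        assert all(lab[0] == "stationary" for lab in labels)

    def test_moving_low_marker_is_lure(self):
        frames = [[[0.5 + 0.03 * i, 1.0, 0.05]] for i in range(40)]
        labels = label_markers(make_cloud(frames), default_templates())
        assert all(lab[0] == "lure" for lab in labels)

    def test_backpack_template_matched_and_stray_unassigned(self):
        stray = [2.0, 2.0, 1.5]
        frames = []
        for i in range(30):
            pts = (BACKPACK_OFFSETS + [0.03 * i, 1.0, 0.8]).tolist()
            pts.append(stray_i := [stray[0] + 0.05 * i, stray[1], stray[2]])
            frames.append(pts)
        labels = label_markers(make_cloud(frames), default_templates())
        for lab in labels:
            assert list(lab[:4]) == ["backpack"] * 4
            assert lab[4] == "unassigned"

    def test_labelling_invariant_to_point_order(self):
        rng = np.random.default_rng(5)
        frames = []
        for i in range(25):
            pts = (BACKPACK_OFFSETS + [0.04 * i, 1.0, 0.8]).tolist()
            pts.append([3.0, 3.0, 0.05 + 0.0])  # fixed low point -> stationary
            pts.append([0.5 + 0.05 * i, 2.0, 0.04])  # moving low point -> lure
            frames.append(pts)
        cloud = make_cloud(frames)
        base = label_markers(cloud, default_templates())
        perms = [rng.permutation(len(f)) for f in cloud.frames]
        shuffled = MarkerCloud(cloud.times, [f[p] for f, p in zip(cloud.frames, perms)])
        out = label_markers(shuffled, default_templates())
        for lab_b, lab_s, p in zip(base, out, perms):
            assert list(lab_s) == list(lab_b[p])

    def test_empty_cloud_raises(self):
        with pytest.raises(EmptyCloudError):
            label_markers(MarkerCloud(np.empty(0), []), default_templates())

    def test_template_needs_distinct_points(self):
        with pytest.raises(ValueError):
            Template.from_points("bad", np.zeros((3, 3)))


def smooth_track(n=120, speed=(2.0, 0.5)):
    t = np.arange(n) * DT
    xyz = np.column_stack([1.0 + speed[0] * t, 2.0 + speed[1] * t, 0.7 + 0 * t])
    return t, xyz


class TestCleaning:
    def centroids(self, bird):
        t = np.arange(len(bird)) * DT
        lure = np.column_stack([0.5 + 3.0 * t, np.full(len(t), 1.0), np.full(len(t), 0.05)])
        return LabelledCentroids(t, bird, lure)

    def test_extreme_spike_removed_in_first_pass(self):
        _, bird = smooth_track()
        bird[60] += [0.6, 0.0, 0.0]
        out = clean_trajectory(self.centroids(bird))
        assert np.isnan(out.bird[60]).all()
        assert np.isfinite(out.bird[[59, 61]]).all()

    def test_moderate_spike_survives_first_pass_only(self):
        _, bird = smooth_track()
        bird[60] += [0.0, 0.1, 0.0]
        cents = self.centroids(bird)
        pass1 = clean_trajectory(cents, thresholds=(0.5,))
        assert np.isfinite(pass1.bird[60]).all()
        out = clean_trajectory(cents)
        assert np.isnan(out.bird[60]).all()

    def test_clean_track_unchanged_and_idempotent(self):
        _, bird = smooth_track()
        bird[40] += [0.0, 0.09, 0.0]
        once = clean_trajectory(self.centroids(bird))
        assert np.isnan(once.bird[40]).all()
        mask = np.isfinite(once.bird[:, 0])
        assert np.array_equal(once.bird[mask], bird[mask])  # survivors untouched
        twice = clean_trajectory(once)
        assert np.array_equal(
            np.isnan(twice.bird), np.isnan(once.bird)
        ) and np.array_equal(twice.bird[mask], once.bird[mask])

    def test_all_missing_series_passes_through(self):
        bird = np.full((30, 3), np.nan)
        out = clean_trajectory(self.centroids(bird))
        assert np.isnan(out.bird).all()


class TestSmoothing:
    def test_constant_velocity_recovered_exactly(self):
        t, xyz = smooth_track(n=100, speed=(3.0, -1.0))
        track = smooth_and_differentiate(t, xyz, tolerance=0.03, out_rate=2000.0)
        assert np.max(np.abs(track.vel[:, 0] - 3.0)) < 1e-6
        assert np.max(np.abs(track.vel[:, 1] + 1.0)) < 1e-6

    def test_quadratic_acceleration_recovered_from_noise(self):
        """Oracle: the generating polynomial x(t) = a t^2 / 2 has constant
        acceleration a; the spline's analytic second derivative must agree
        within 5% despite 5 mm measurement noise. The tolerance is the
        noise-consistent residual budget 2*sigma*sqrt(n) of the
        root-sum-of-squares convention."""
        a = 4.0
        sigma = 0.005
        n = 400
        t = np.arange(n) * DT
        rng = np.random.default_rng(11)
        x = 0.5 * a * t**2 + rng.normal(0, sigma, n)
        tol = 2 * sigma * np.sqrt(n)
        track = smooth_and_differentiate(t, x[:, None], tolerance=tol, out_rate=1000.0)
        interior = slice(len(track.times) // 4, -len(track.times) // 4)
        est = np.mean(track.acc[interior, 0])
        assert abs(est - a) < 0.05 * a

    def test_output_grid_at_20khz(self):
        t, xyz = smooth_track(n=50)
        track = smooth_and_differentiate(t, xyz, tolerance=0.01, out_rate=20000.0)
        assert np.allclose(np.diff(track.times), 5e-5)

    def test_interior_gaps_filled_by_cubic_interpolation(self):
        t, xyz = smooth_track(n=80)
        xyz[30:33] = np.nan
        track = smooth_and_differentiate(t, xyz, tolerance=0.01, out_rate=1000.0)
        idx = np.argmin(np.abs(track.times - t[31]))
        true = np.array([1.0 + 2.0 * t[31], 2.0 + 0.5 * t[31]])
        assert np.allclose(track.pos[idx, :2], true, atol=1e-3)

    def test_too_few_frames_raises(self):
        t, xyz = smooth_track(n=5)
        with pytest.raises(InsufficientDataError):
            smooth_and_differentiate(t, xyz, tolerance=0.01)


def approach_tracks(min_dist_mm):
    """Hawk closing head-on on a stationary lure to a given miss distance."""
    n = 400
    t = np.arange(n) * DT
    lure_xyz = np.column_stack([np.full(n, 6.0), np.full(n, 2.0), np.full(n, 0.05)])
    gap = np.maximum(6.0 - 4.0 * t, min_dist_mm / 1000.0)
    bird_xyz = np.column_stack([6.0 - gap, np.full(n, 2.0), np.full(n, 0.7)])
    bird = smooth_and_differentiate(t, bird_xyz, 0.03, out_rate=1000.0)
    lure = smooth_and_differentiate(t, lure_xyz, 0.01, out_rate=1000.0)
    return bird, lure


class TestQC:
    def test_low_reconstruction_rejected(self):
        bird, lure = approach_tracks(10.0)
        with pytest.raises(FlightRejected, match="template"):
            qc_and_crop(bird, lure, reconstruction_fraction=0.40, out_dt=1e-3)

    def test_intercept_accepted_and_cropped_at_first_contact_frame(self):
        bird, lure = approach_tracks(25.0)
        flight = qc_and_crop(bird, lure, reconstruction_fraction=0.9, out_dt=1e-3)
        d = np.linalg.norm(flight.hawk_frames[-1] - flight.lure_frames[-1])
        assert d <= 0.030
        # cropped at the *first* frame within 30 mm
        before = np.linalg.norm(
            flight.hawk_frames[:-1] - flight.lure_frames[:-1], axis=1
        )
        assert np.all(before > 0.030)
        assert flight.intercept_time == pytest.approx(flight.times[-1])

    def test_near_miss_rejected(self):
        bird, lure = approach_tracks(31.0)
        with pytest.raises(FlightRejected, match="no intercept"):
            qc_and_crop(bird, lure, reconstruction_fraction=0.9, out_dt=1e-3)
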