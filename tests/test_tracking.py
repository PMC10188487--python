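"""Tracking stage: preprocessing, detection, linking, metrics, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gastruquant.tracking import (DetectionParams, Trajectory,
                                  classify_displacement_bin, classify_position,
                                  compare_groups, compute_track_metrics,
                                  detect_spots, filter_tracks, link_tracks,
                                  preprocess_frame)

PARAMS = DetectionParams()


def traj(points, dt=4.0, tid=0):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return Trajectory(tid, np.arange(n), np.arange(n) * dt, pts)


class TestPreprocessFrame:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 7.0)
        out = preprocess_frame([img, img])
        np.testing.assert_allclose(out, 7.0, atol=1e-9)

    def test_max_projection_picks_brighter_section(self):
        a = np.full((32, 32), 1.0)
        b = np.full((32, 32), 2.0)
        out = preprocess_frame([a, b])
        np.testing.assert_allclose(out, 2.0, atol=1e-9)

    def test_sharpening_matches_reference_unsharp(self):
        # our (in - w*blur)/(1-w) equals skimage unsharp_mask with
        # amount = w/(1-w) before the median step
        from skimage.filters import unsharp_mask
        from scipy import ndimage as ndi
        rng = np.random.default_rng(0)
        img = rng.random((80, 80)) + 5.0
        blurred = ndi.gaussian_filter(img, 15.0, mode="reflect")
        mine = (img - 0.6 * blurred) / 0.4
        ref = unsharp_mask(img, radius=15.0, amount=1.5, preserve_range=True)
        np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_blob_contrast_enhanced(self):
        yy, xx = np.mgrid[:101, :101]
        blob = np.exp(-((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * 4.0**2))
        out = preprocess_frame([blob, blob])
        raw_contrast = blob[50, 50] - blob[5, 5]
        out_contrast = out[50, 50] - out[5, 5]
        assert out_contrast > raw_contrast

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frame([np.zeros((10, 10)), np.zeros((12, 10))])


class TestDetectSpots:
    def test_blank_frame_gives_no_spots(self):
        assert detect_spots(np.zeros((64, 64)), PARAMS).empty

    def test_planted_blobs_recovered(self, snr5_scene):
        stack, truth, render = snr5_scene
        frame = stack[0]
        spots = detect_spots(frame, PARAMS)
        tt = truth[truth.frame == 0][["x_um", "y_um"]].to_numpy()
        dd = spots[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(tt[:, None] - dd[None], axis=2)
        recovered = np.sum(d.min(axis=1) <= render.pixel_size_um)
        assert recovered >= 0.95 * len(tt)

    def test_close_pair_merges(self):
        # two blobs half a diameter apart yield at most one detection
        px = PARAMS.pixel_size_um
        sep_px = 0.5 * PARAMS.blob_diameter_px
        yy, xx = np.mgrid[:128, :128]
        img = np.zeros((128, 128))
        for cx in (60.0, 60.0 + sep_px):
            img += np.exp(-((xx - cx) ** 2 + (yy - 64) ** 2) / (2 * 2.8**2))
        spots = detect_spots(img, PARAMS)
        near = np.linalg.norm(
            spots[["x_um", "y_um"]].to_numpy()
            - np.array([62.0 * px, 64.0 * px]), axis=1)
        assert np.sum(near < 8 * px) <= 1


class TestLinkTracks:
    def test_two_well_separated_cells(self):
        det = {f: np.array([[10.0 + f, 10.0], [60.0 + f, 60.0]])
               for f in range(10)}
        tracks = link_tracks(det, PARAMS)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(tr) == 10
            steps = np.diff(tr.xy_um, axis=0)
            np.testing.assert_allclose(steps, [[1.0, 0.0]] * 9, atol=1e-12)

    def test_gap_splits_track(self):
        det = {f: np.array([[10.0 + f, 10.0]]) for f in range(10) if f != 5}
        tracks = link_tracks(det, PARAMS)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [4, 5]

    def test_link_distance_gate(self):
        det = {0: np.array([[10.0, 10.0]]), 1: np.array([[40.0, 10.0]])}
        tracks = link_tracks(det, PARAMS)   # 30 µm jump > 15 µm gate
        assert len(tracks) == 2

    def test_simulated_identity_agreement(self, snr5_scene):
        stack, truth, render = snr5_scene
        det = {i: detect_spots(stack[i], PARAMS)[["x_um", "y_um"]].to_numpy()
               for i in range(stack.shape[0])}
        linked = link_tracks(det, PARAMS)
        by_frame = {f: g for f, g in truth.groupby("frame")}

        def true_id(f, xy):
            g = by_frame[f]
            d = np.linalg.norm(g[["x_um", "y_um"]].to_numpy() - xy, axis=1)
            i = d.argmin()
            return g["track_id"].iloc[i] if d[i] <= 2 * render.pixel_size_um \
                else None

        ok = tot = 0
        for tr in linked:
            for k in range(len(tr) - 1):
                a = true_id(tr.frames[k], tr.xy_um[k])
                b = true_id(tr.frames[k + 1], tr.xy_um[k + 1])
                tot += 1
                ok += (a is not None and a == b)
        assert ok / tot >= 0.95


class TestTrackMetrics:
    def test_pythagorean_track(self):
        m = compute_track_metrics(traj([(0, 0), (3, 4)]), PARAMS)
        assert m.displacement_um == pytest.approx(5.0)
        assert m.path_length_um == pytest.approx(5.0)
        assert m.persistence == pytest.approx(1.0)
        assert m.mean_velocity_um_min == pytest.approx(1.25)

    def test_closed_loop(self):
        square = [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]
        m = compute_track_metrics(traj(square), PARAMS)
        assert m.displacement_um == pytest.approx(0.0)
        assert m.path_length_um == pytest.approx(40.0)
        assert m.persistence == pytest.approx(0.0)

    def test_path_length_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 2, (1001, 2)), axis=0)
        m = compute_track_metrics(traj(pts), PARAMS)
        brute = sum(
            float(np.hypot(pts[i + 1, 0] - pts[i, 0],
                           pts[i + 1, 1] - pts[i, 1]))
            for i in range(len(pts) - 1))
        assert m.path_length_um == pytest.approx(brute, abs=1e-9)

    def test_single_point_track_rejected(self):
        with pytest.raises(ValueError):
            compute_track_metrics(traj([(0, 0)]), PARAMS)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-500, 500), st.floats(-500, 500),
           st.floats(0, 2 * np.pi))
    def test_rigid_motion_invariance(self, seed, dx, dy, angle):
        """D, L, P, v are invariant under translation and rotation."""
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 2, (20, 2)), axis=0)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + [dx, dy]
        m0 = compute_track_metrics(traj(pts), PARAMS)
        m1 = compute_track_metrics(traj(moved), PARAMS)
        assert m0.displacement_um == pytest.approx(m1.displacement_um, abs=1e-9)
        assert m0.path_length_um == pytest.approx(m1.path_length_um, abs=1e-9)
        assert m0.persistence == pytest.approx(m1.persistence, abs=1e-9)

    def test_displacement_never_exceeds_path_length(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            pts = np.cumsum(rng.normal(0, 3, (15, 2)), axis=0)
            m = compute_track_metrics(traj(pts), PARAMS)
            assert m.displacement_um <= m.path_length_um + 1e-12


class TestDisplacementBins:
    @pytest.mark.parametrize("d,expected", [
        (0, "sub"), (19.99, "sub"), (20, "blue"), (49.99, "blue"),
        (50, "green"), (60, "green"), (79.99, "green"), (80, "yellow"),
        (130, "yellow"), (130.01, "red"), (131, "red"), (500, "red"),
    ])
    def test_bin_boundaries(self, d, expected):
        assert classify_displacement_bin(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_displacement_bin(-1)


class TestFiltersAndPosition:
    def _metrics(self, n_frames, start_x):
        pts = [(start_x + i * 0.1, 0.0) for i in range(n_frames)]
        return compute_track_metrics(traj(pts), PARAMS)

    def test_short_track_excluded(self):
        short = self._metrics(14, 500.0)
        kept = filter_tracks([short], PARAMS)
        assert kept == []

    def test_fifteen_frames_retained(self):
        ok = self._metrics(15, 500.0)
        assert filter_tracks([ok], PARAMS) == [ok]

    def test_midline_start_excluded(self):
        near = self._metrics(20, 10.0)   # midline at x=0, halfwidth 50
        assert filter_tracks([near], PARAMS) == []

    def test_idempotent(self):
        ms = [self._metrics(n, x) for n, x in
              [(20, 500.0), (10, 500.0), (30, 5.0), (16, 200.0)]]
        once = filter_tracks(ms, PARAMS)
        assert filter_tracks(once, PARAMS) == once

    def test_classify_position(self):
        centered = traj([(0.0, i) for i in range(5)])
        assert classify_position(centered, PARAMS) == "midline"
        away = traj([(200.0, i) for i in range(5)])
        assert classify_position(away, PARAMS) == "lateral"

    def test_straddling_track_uses_mean(self):
        pts = [(x, 0.0) for x in (-80.0, -40, 0, 40, 80, 120)]
        mean_dev = np.mean(np.abs([p[0] for p in pts]))
        expected = "midline" if mean_dev <= 50.0 else "lateral"
        assert classify_position(traj(pts), PARAMS) == expected


class TestCompareGroups:
    def test_identical_groups(self):
        rep = compare_groups([1.0, 2, 3], [1.0, 2, 3])
        assert rep["t_statistic"] == 0.0
        assert rep["t_p"] == 1.0

    def test_shifted_groups_significant(self):
        rep = compare_groups([1.0, 2, 3], [11.0, 12, 13])
        assert rep["t_p"] < 0.01

    def test_too_few_embryos_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
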