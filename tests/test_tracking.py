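"""Synthetic marker rendering and mean-shift tracking."""

import numpy as np
import pytest
from skimage.color import hsv2rgb

from pntcal import (BackgroundSpec, MarkerSpec, PistonMotion, TrackWindow,
                    render_frames, track, trajectory_to_displacement)
from pntcal.exceptions import TrackingError
from pntcal.tracking import (Trajectory, back_projection, hue_histogram,
                             meanshift_step, to_hsv)
from conftest import brute_force_marker_centroid

MARKER = MarkerSpec()


def red_frame(h=60, w=80, color=(210, 30, 30)):
    frame = np.zeros((h, w, 3), dtype=np.uint8)
    frame[:] = color
    return frame


class TestRenderer:
    def test_same_seed_identical_bytes(self):
        m = PistonMotion(amplitude=5.0, frequency=0.5)
        a = render_frames(m, seed=11)
        b = render_frames(m, seed=11)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_marker_centroid_matches_analytic_position(self):
        m = PistonMotion(amplitude=10.0, frequency=0.4)
        seq = render_frames(m, seed=2)
        true_cols = np.asarray(seq.meta["true_cols"])
        for k in (0, seq.n // 2, seq.n - 1):
            _, c = brute_force_marker_centroid(seq.frames[k], MARKER.color)
            assert abs(c - true_cols[k]) <= 0.5

    def test_near_static_motion_constant_frames(self):
        m = PistonMotion(amplitude=1e-6, frequency=0.5)
        seq = render_frames(m, background=BackgroundSpec(noise_sigma=0.0),
                            seed=0)
        # sub-microscopic motion: at most 1 LSB of anti-aliasing change
        diff = seq.frames[0].astype(int) - seq.frames[-1].astype(int)
        assert np.abs(diff).max() <= 1

    def test_marker_leaving_frame_rejected(self):
        from pntcal.exceptions import RenderError
        m = PistonMotion(amplitude=18.75, frequency=0.3)
        with pytest.raises(RenderError):
            render_frames(m, px_per_cm=20.0)   # 750 px travel, 320 px frame

    def test_similar_hue_background_rejected(self):
        m = PistonMotion(amplitude=5.0, frequency=0.5)
        with pytest.raises(ValueError):
            render_frames(m, background=BackgroundSpec(color=(220, 60, 40),
                                                       noise_sigma=0))


class TestFrameIO:
    def test_png_sequence_round_trip(self, tmp_path):
        m = PistonMotion(amplitude=2.0, frequency=1.0)
        seq = render_frames(m, seed=9)
        seq.save(tmp_path / "video")
        from pntcal import FrameSequence
        back = FrameSequence.load(tmp_path / "video")
        np.testing.assert_array_equal(back.frames, seq.frames)
        assert back.fps == seq.fps
        assert back.px_per_cm == seq.px_per_cm


class TestColorOps:
    def test_hsv_reference_colors(self):
        hsv = to_hsv(red_frame(2, 2, (255, 0, 0)))
        assert hsv[0, 0, 0] == pytest.approx(0.0)
        assert hsv[0, 0, 1] == pytest.approx(1.0)
        assert hsv[0, 0, 2] == pytest.approx(1.0)
        gray = to_hsv(red_frame(2, 2, (128, 128, 128)))
        assert gray[0, 0, 1] == 0.0

    def test_hsv_round_trip_stable(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        hsv = to_hsv(rgb)
        back = np.round(hsv2rgb(np.dstack([hsv[..., 0] / 360.0,
                                           hsv[..., 1], hsv[..., 2]]))
                        * 255).astype(int)
        assert np.abs(back - rgb.astype(int)).max() <= 1

    def test_pure_marker_histogram_single_bin(self):
        hsv = to_hsv(red_frame())
        hist = hue_histogram(hsv, TrackWindow(center=(30, 40)), bins=16)
        assert hist.sum() == pytest.approx(1.0)
        assert hist[0] == pytest.approx(1.0)   # red hue ≈ 0° → first bin

    def test_half_red_half_green_histogram(self):
        frame = red_frame(40, 40, (210, 30, 30))
        frame[:, 20:] = (30, 210, 30)
        hist = hue_histogram(to_hsv(frame), TrackWindow(center=(20, 20),
                                                        half_extent=(10, 10)),
                             bins=16)
        top = np.sort(hist)[-2:]
        np.testing.assert_allclose(top, 0.5, atol=0.05)

    def test_gray_window_degenerate(self):
        hsv = to_hsv(red_frame(20, 20, (120, 120, 120)))
        hist = hue_histogram(hsv, TrackWindow(center=(10, 10),
                                              half_extent=(5, 5)))
        assert hist.sum() == 0.0

    def test_back_projection_selects_marker(self):
        m = PistonMotion(amplitude=5.0, frequency=0.5)
        seq = render_frames(m, seed=4)
        hsv = to_hsv(seq.frames[0])
        r0 = seq.meta["true_row"]
        c0 = seq.meta["true_cols"][0]
        hist = hue_histogram(hsv, TrackWindow(center=(r0, c0)))
        w = back_projection(hsv, hist)
        assert w.min() >= 0.0 and w.max() <= 1.0
        rmax, cmax = np.unravel_index(np.argmax(w), w.shape)
        assert abs(rmax - r0) <= MARKER.size_px[0]
        assert abs(cmax - c0) <= MARKER.size_px[1]
        # neutral background pixels carry zero weight
        assert w[2, 2] == 0.0


class TestMeanShift:
    def _blob(self, center, shape=(60, 80)):
        r, c = np.mgrid[0:shape[0], 0:shape[1]]
        return np.exp(-(((r - center[0]) ** 2 + (c - center[1]) ** 2)
                        / 18.0))

    def test_centered_blob_fixed_point(self):
        w = self._blob((30, 40))
        win, lost = meanshift_step(w, TrackWindow(center=(30, 40),
                                                  half_extent=(12, 12)))
        assert not lost
        assert win.center[0] == pytest.approx(30, abs=0.05)
        assert win.center[1] == pytest.approx(40, abs=0.05)

    def test_offset_blob_contracts_toward_centroid(self):
        w = self._blob((30, 43))
        win = TrackWindow(center=(30, 40), half_extent=(12, 12))
        dist = abs(win.center[1] - 43)
        for _ in range(5):
            win, lost = meanshift_step(w, win)
            assert not lost
            new_dist = abs(win.center[1] - 43)
            assert new_dist <= dist + 1e-9
            dist = new_dist
        assert dist < 0.2

    def test_empty_window_flags_lost(self):
        w = np.zeros((60, 80))
        win, lost = meanshift_step(w, TrackWindow(center=(30, 40)))
        assert lost and win.center == (30, 40)


class TestTrack:
    def test_static_marker_constant_trajectory(self):
        m = PistonMotion(amplitude=1e-6, frequency=0.5)
        seq = render_frames(m, background=BackgroundSpec(noise_sigma=0.0),
                            seed=0)
        init = TrackWindow(center=(seq.meta["true_row"],
                                   seq.meta["true_cols"][0]))
        traj = track(seq, init)
        assert np.ptp(traj.cols) < 0.1

    def test_tracks_sinusoid_within_one_pixel_rms(self, rendered_sequence):
        seq = rendered_sequence
        init = TrackWindow(center=(seq.meta["true_row"],
                                   seq.meta["true_cols"][0]))
        traj = track(seq, init)
        err = traj.cols - np.asarray(seq.meta["true_cols"])
        assert np.sqrt(np.mean(err ** 2)) <= 1.0

    def test_agrees_with_brute_force_centroid_oracle(self,
                                                     rendered_sequence):
        seq = rendered_sequence
        init = TrackWindow(center=(seq.meta["true_row"],
                                   seq.meta["true_cols"][0]))
        traj = track(seq, init)
        oracle = np.array([brute_force_marker_centroid(f, MARKER.color)[1]
                           for f in seq.frames])
        err = traj.cols - oracle
        assert np.sqrt(np.mean(err ** 2)) <= 1.0

    def test_vanishing_marker_raises(self):
        m = PistonMotion(amplitude=3.0, frequency=0.5)
        seq = render_frames(m, background=BackgroundSpec(noise_sigma=0.0),
                            seed=0)
        frames = seq.frames.copy()
        frames[5:] = 128     # marker disappears into the background
        seq2 = type(seq)(frames=frames, fps=seq.fps,
                         px_per_cm=seq.px_per_cm, meta=seq.meta)
        init = TrackWindow(center=(seq.meta["true_row"],
                                   seq.meta["true_cols"][0]))
        with pytest.raises(TrackingError):
            track(seq2, init)


class TestDisplacement:
    def test_constant_trajectory_zero_displacement(self):
        traj = Trajectory(centers=np.tile([10.0, 20.0], (5, 1)), fps=60)
        disp = trajectory_to_displacement(traj, 10.0)
        np.testing.assert_allclose(disp.values, 0.0)

    def test_pixel_scale_arithmetic(self):
        centers = np.array([[10.0, 20.0], [10.0, 120.0]])
        disp = trajectory_to_displacement(Trajectory(centers, fps=60), 10.0)
        assert disp.values[-1] == pytest.approx(10.0)
        assert disp.unit == "cm"

    def test_full_stroke_recovers_plunger_travel(self, rendered_sequence):
        seq = rendered_sequence
        init = TrackWindow(center=(seq.meta["true_row"],
                                   seq.meta["true_cols"][0]))
        traj = track(seq, init)
        disp = trajectory_to_displacement(traj, seq.px_per_cm)
        assert np.max(np.abs(disp.values)) == pytest.approx(37.5, rel=0.002)

    def test_scale_equivariance(self):
        m = PistonMotion(amplitude=18.75, frequency=0.3)
        results = []
        for scale in (1, 2):
            seq = render_frames(
                m, shape=(180 * scale, 320 * scale), px_per_cm=7.0 * scale,
                background=BackgroundSpec(noise_sigma=0.0), seed=0)
            init = TrackWindow(center=(seq.meta["true_row"],
                                       seq.meta["true_cols"][0]))
            traj = track(seq, init)
            disp = trajectory_to_displacement(traj, seq.px_per_cm)
            results.append(np.max(np.abs(disp.values)))
        assert abs(results[0] - results[1]) / results[0] < 1e-3
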