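"""Kymograph construction: preprocessing, geometry, circular sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zring
from zring.simulate import ConfigError
from zring.kymo import spatial_mean_filter

from conftest import roi_for, true_slope


def make_movie(data, pixel_size=65.0, frame_interval=3.0):
    return zring.MovieStack(np.asarray(data, dtype=float), pixel_size, frame_interval)


class TestTemporalAverage:
    def test_window_one_is_identity(self, noisy_movie):
        _, movie = noisy_movie
        out = zring.temporal_average(movie, 1)
        np.testing.assert_array_equal(out.data, movie.data)
        assert out.frame_interval == movie.frame_interval

    def test_constant_movie_unchanged(self):
        movie = make_movie(np.full((9, 4, 4), 7.0))
        out = zring.temporal_average(movie, 3)
        np.testing.assert_allclose(out.data, 7.0)

    def test_block_means_and_interval_scaling(self):
        frames = np.stack([np.full((4, 4), v) for v in range(1, 11)])
        out = zring.temporal_average(make_movie(frames), 5)
        assert out.n_frames == 2
        np.testing.assert_allclose(out.data[0], 3.0)
        np.testing.assert_allclose(out.data[1], 8.0)
        assert out.frame_interval == pytest.approx(15.0)

    def test_trailing_partial_block_dropped(self):
        movie = make_movie(np.zeros((10, 4, 4)))
        assert zring.temporal_average(movie, 4).n_frames == 2

    def test_window_exceeding_length_errors(self):
        movie = make_movie(np.zeros((5, 4, 4)))
        with pytest.raises(ConfigError, match="window"):
            zring.temporal_average(movie, 6)


class TestDriftCorrect:
    def test_zero_drift_zero_shifts(self, noise_free_movie):
        _, movie = noise_free_movie
        _, shifts = zring.drift_correct(movie)
        assert np.abs(shifts).max() < 0.1

    def test_known_integer_shifts_recovered(self, static_noise_free_movie):
        _, movie = static_noise_free_movie
        frame0 = movie.data[0]
        applied = [(0, 0), (1, 0), (2, -1), (3, 2), (-2, 1)]
        drifted = np.stack(
            [np.roll(frame0, s, axis=(0, 1)) for s in applied]
        )
        corrected, shifts = zring.drift_correct(
            make_movie(drifted, movie.pixel_size, movie.frame_interval)
        )
        np.testing.assert_allclose(shifts, [(-r, -c) for r, c in applied],
                                   atol=0.1)
        # inverse consistency: registered frames match frame 0 away from edges
        for t in range(1, 5):
            np.testing.assert_allclose(
                corrected.data[t][8:-8, 8:-8], frame0[8:-8, 8:-8], atol=1.0
            )

    def test_constant_frames_warn_and_zero_shift(self, caplog):
        movie = make_movie(np.full((3, 8, 8), 2.0))
        with caplog.at_level("WARNING"):
            _, shifts = zring.drift_correct(movie)
        assert np.all(shifts == 0)
        assert any("constant frame" in r.message for r in caplog.records)


class TestCircleFromTwoPoints:
    def test_horizontal_diameter(self):
        roi = zring.circle_from_two_points((0, 0), (0, 10))
        assert roi.center == (0.0, 5.0)
        assert roi.radius_px == 5.0

    def test_three_four_five(self):
        roi = zring.circle_from_two_points((3, 4), (-3, -4))
        assert roi.center == (0.0, 0.0)
        assert roi.radius_px == pytest.approx(5.0)

    def test_subpixel_diagonal(self):
        roi = zring.circle_from_two_points((2.5, 2.5), (7.5, 7.5))
        assert roi.radius_px == pytest.approx(2.5 * np.sqrt(2))

    def test_center_edge_mode(self):
        roi = zring.circle_from_two_points((10, 10), (10, 14), mode="center_edge")
        assert roi.center == (10.0, 10.0)
        assert roi.radius_px == 4.0

    def test_identical_points_error(self):
        with pytest.raises(ConfigError, match="distinct"):
            zring.circle_from_two_points((1, 1), (1, 1))

    def test_out_of_bounds_names_margin(self):
        with pytest.raises(ConfigError, match="margin"):
            zring.circle_from_two_points((5, 0), (5, 10), image_shape=(12, 12))

    @given(
        st.tuples(st.floats(10, 20), st.floats(10, 20)),
        st.tuples(st.floats(30, 40), st.floats(30, 40)),
    )
    @settings(max_examples=25, deadline=None)
    def test_midpoint_and_half_distance(self, p1, p2):
        roi = zring.circle_from_two_points(p1, p2)
        assert roi.center[0] == pytest.approx((p1[0] + p2[0]) / 2)
        assert roi.center[1] == pytest.approx((p1[1] + p2[1]) / 2)
        d = np.hypot(p2[0] - p1[0], p2[1] - p1[1])
        assert roi.radius_px == pytest.approx(d / 2)


class TestSampleTrajectory:
    def test_constant_frame(self):
        roi = zring.RingROI(center=(16, 16), radius_px=6)
        prof = zring.sample_trajectory(np.full((32, 32), 3.5), roi)
        np.testing.assert_allclose(prof, 3.5)
        assert prof.size == roi.n_arc_samples

    def test_exact_on_linear_ramp(self):
        """Bilinear interpolation reproduces an affine image exactly, so the
        profile of I(row, col) = col is c_c + rho*cos(theta)."""
        frame = np.tile(np.arange(32, dtype=float), (32, 1))
        roi = zring.RingROI(center=(15.3, 16.2), radius_px=7.5)
        prof = zring.sample_trajectory(frame, roi)
        theta = 2 * np.pi * np.arange(roi.n_arc_samples) / roi.n_arc_samples
        np.testing.assert_allclose(prof, 16.2 + 7.5 * np.cos(theta), atol=1e-9)

    def test_radially_symmetric_ring_offsets_agree(self):
        rr, cc = np.mgrid[:64, :64]
        rho = np.hypot(rr - 32.0, cc - 32.0)
        frame = np.exp(-0.5 * ((rho - 8) / 4) ** 2)
        roi = zring.RingROI(center=(32.0, 32.0), radius_px=8.0)
        lo = zring.sample_trajectory(frame, roi, -1.0)
        hi = zring.sample_trajectory(frame, roi, +1.0)
        np.testing.assert_allclose(lo, hi, atol=0.01)

    def test_outside_image_errors(self):
        roi = zring.RingROI(center=(4, 4), radius_px=6)
        with pytest.raises(ConfigError, match="outside"):
            zring.sample_trajectory(np.zeros((16, 16)), roi)


class TestBuildKymograph:
    def test_static_movie_rows_identical(self, static_noise_free_movie):
        cfg, movie = static_noise_free_movie
        kym = zring.build_kymograph(movie, roi_for(cfg))
        for t in range(1, kym.n_rows):
            np.testing.assert_allclose(kym.data[t], kym.data[0], rtol=1e-10)

    def test_uniform_background_constant_matrix(self):
        movie = make_movie(np.full((10, 32, 32), 4.0))
        roi = zring.RingROI(center=(16, 16), radius_px=6)
        kym = zring.build_kymograph(movie, roi)
        np.testing.assert_allclose(kym.data, 4.0)

    def test_calibration_identity(self, noise_free_movie):
        cfg, movie = noise_free_movie
        roi = roi_for(cfg)
        kym = zring.build_kymograph(movie, roi)
        assert kym.arc_step * roi.n_arc_samples == pytest.approx(
            2 * np.pi * roi.radius_px * movie.pixel_size
        )

    def test_rotation_appears_as_cyclic_column_shift(self):
        """Pick a speed whose per-frame column shift is an integer so row t
        of the noise-free kymograph is row 0 rolled by t*shift columns."""
        base = zring.RingSimConfig(noise=False, bleach_rate=0.0)
        roi = roi_for(base)
        arc_step = 2 * np.pi * roi.radius_px * base.pixel_size / roi.n_arc_samples
        shift_cols = 2
        speed = shift_cols * arc_step / base.frame_interval
        cfg = zring.RingSimConfig(noise=False, bleach_rate=0.0, speed=speed)
        kym = zring.build_kymograph(zring.simulate_ring_movie(cfg), roi)
        for t in (1, 5, 20):
            np.testing.assert_allclose(
                kym.data[t], np.roll(kym.data[0], t * shift_cols),
                rtol=0.02, atol=0.3,
            )

    def test_three_trajectory_average_reduces_noise(self):
        """On a noisy static ring the 3-trajectory average has lower
        temporal variance than the single-r trajectory."""
        cfg = zring.RingSimConfig(speed=0.0, bleach_rate=0.0, seed=2)
        movie = zring.simulate_ring_movie(cfg)
        roi = roi_for(cfg)
        kym3 = zring.build_kymograph(movie, roi)
        single = np.stack(
            [zring.sample_trajectory(movie.data[t], roi) for t in range(movie.n_frames)]
        )
        assert kym3.data.var(axis=0).mean() < single.var(axis=0).mean()

    def test_spatial_mean_filter_preserves_calibration(self, noisy_movie):
        _, movie = noisy_movie
        out = spatial_mean_filter(movie)
        assert out.frame_interval == movie.frame_interval
        assert out.data.shape == movie.data.shape
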