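"""Window grid, entropy maps, interpolation, scan conversion, ROI stats."""

import numpy as np
import pytest

from entroscan.entropy import HistogramConfig, KDEConfig, entropy_hist, entropy_kde
from entroscan.errors import EntroscanError
from entroscan.imaging import (
    WindowSpec,
    colorize,
    compute_entropy_map,
    grid_from_samples,
    interpolate_map,
    roi_stats,
    scan_convert,
    window_grid,
)
from entroscan.io import AcquisitionMeta, EnvelopeFrame


class TestWindowGrid:
    def test_stride_rule_example(self):
        # 1000x100 frame, 100x10-sample window, 90% overlap -> strides 10 and
        # 1, 91 positions on each axis
        grid = grid_from_samples((1000, 100), (100, 10), overlap=(0.9, 0.9))
        assert grid.shape == (91, 91)
        assert grid.axial_starts[1] - grid.axial_starts[0] == 10
        assert grid.lateral_starts[1] - grid.lateral_starts[0] == 1

    def test_zero_overlap_tiles_without_gaps(self):
        grid = grid_from_samples((100, 40), (20, 8), overlap=(0.0, 0.0))
        np.testing.assert_array_equal(grid.axial_starts, np.arange(0, 81, 20))
        np.testing.assert_array_equal(grid.lateral_starts, np.arange(0, 33, 8))

    def test_window_equal_to_frame_gives_single_window(self):
        grid = grid_from_samples((64, 16), (64, 16))
        assert grid.shape == (1, 1)

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(EntroscanError, match="window exceeds frame"):
            grid_from_samples((64, 16), (65, 16))

    def test_physical_window_conversion(self, meta):
        # 2.3 mm / 0.0641666 mm per sample = 35.84 -> 36 samples axially;
        # 2.3 mm / 0.3 mm pitch = 7.67 -> 8 scanlines laterally
        grid = window_grid((384, 32), meta, WindowSpec())
        assert grid.window_samples == (36, 8)
        assert grid.axial_starts[1] - grid.axial_starts[0] == 4
        assert grid.lateral_starts[1] - grid.lateral_starts[0] == 1


class TestComputeEntropyMap:
    def test_serial_and_parallel_maps_bit_identical(self, rayleigh_envelope):
        spec = WindowSpec()
        serial = compute_entropy_map(rayleigh_envelope, spec, workers=1)
        parallel = compute_entropy_map(rayleigh_envelope, spec, workers=8)
        np.testing.assert_array_equal(serial.values, parallel.values)

    @pytest.mark.parametrize("estimator", ["hist", "kde"])
    def test_matches_plain_sliding_window_oracle(self, rayleigh_envelope, estimator):
        spec = WindowSpec()
        emap = compute_entropy_map(rayleigh_envelope, spec, estimator=estimator)
        grid = emap.grid
        wa, wl = grid.window_samples
        amp = rayleigh_envelope.amplitude
        for r in range(0, grid.shape[0], 7):
            for c in range(0, grid.shape[1], 5):
                win = amp[
                    grid.axial_starts[r] : grid.axial_starts[r] + wa,
                    grid.lateral_starts[c] : grid.lateral_starts[c] + wl,
                ].ravel()
                expected = entropy_kde(win) if estimator == "kde" else entropy_hist(win)
                assert emap.values[r, c] == pytest.approx(expected, abs=1e-10)

    def test_gain_shifts_kde_map_by_log_gain_exactly(self, rayleigh_envelope):
        spec = WindowSpec()
        base = compute_entropy_map(rayleigh_envelope, spec).values
        scaled_env = EnvelopeFrame(
            amplitude=4.0 * rayleigh_envelope.amplitude, meta=rayleigh_envelope.meta
        )
        shifted = compute_entropy_map(scaled_env, spec).values
        np.testing.assert_allclose(shifted - base, np.log(4.0), atol=1e-10)

    def test_translation_by_one_stride_shifts_grid_by_one_cell(self, meta):
        rng = np.random.default_rng(9)
        amp = rng.rayleigh(1.0, (200, 20))
        spec = WindowSpec()
        g = window_grid(amp.shape, meta, spec)
        stride = g.axial_starts[1] - g.axial_starts[0]
        m1 = compute_entropy_map(EnvelopeFrame(amplitude=amp, meta=meta), spec).values
        m2 = compute_entropy_map(
            EnvelopeFrame(amplitude=amp[stride:], meta=meta), spec
        ).values
        np.testing.assert_allclose(m1[1 : 1 + m2.shape[0]], m2, atol=1e-12)

    def test_degenerate_window_yields_sentinels(self, meta):
        amp = np.random.default_rng(1).rayleigh(1.0, (80, 16))
        amp[:40, :] = 1.0  # zero-spread region
        env = EnvelopeFrame(amplitude=amp, meta=meta)
        with pytest.warns(UserWarning, match="zero-spread"):
            kde_map = compute_entropy_map(env, WindowSpec())
        hist_map = compute_entropy_map(env, WindowSpec(), estimator="hist")
        assert np.isnan(kde_map.values[0, 0])
        assert hist_map.values[0, 0] == 0.0

    def test_rayleigh_frame_map_mean_matches_closed_form(self, meta):
        # H(Rayleigh sigma) = 1 + ln(sigma/sqrt(2)) + gamma/2
        rng = np.random.default_rng(17)
        env = EnvelopeFrame(amplitude=rng.rayleigh(1.0, (300, 32)), meta=meta)
        emap = compute_entropy_map(env, WindowSpec())
        truth = 1.0 + np.log(1.0 / np.sqrt(2.0)) + 0.5772156649015329 / 2.0
        assert np.nanmean(emap.values) == pytest.approx(truth, abs=0.05)


class TestInterpolateMap:
    def test_constant_map_interpolates_to_constant(self, rayleigh_envelope):
        emap = compute_entropy_map(rayleigh_envelope, WindowSpec(), estimator="hist")
        const = emap.__class__(
            values=np.full(emap.shape, 2.5), grid=emap.grid,
            estimator="hist", units="bits",
        )
        full = interpolate_map(const, rayleigh_envelope.shape)
        np.testing.assert_allclose(full, 2.5)

    def test_window_center_values_preserved_and_bounded(self, rayleigh_envelope):
        emap = compute_entropy_map(rayleigh_envelope, WindowSpec(), estimator="hist")
        full = interpolate_map(emap, rayleigh_envelope.shape)
        assert full.min() >= emap.values.min() - 1e-12
        assert full.max() <= emap.values.max() + 1e-12
        # centers at integer coordinates reproduce map values exactly
        grid = emap.grid
        for r in range(0, grid.shape[0], 9):
            ac = grid.axial_centers[r]
            if ac != int(ac):
                continue
            for c in range(grid.shape[1]):
                lc = grid.lateral_centers[c]
                if lc == int(lc):
                    assert full[int(ac), int(lc)] == pytest.approx(
                        emap.values[r, c], abs=1e-12
                    )

    def test_bilinear_midpoint_of_checkerboard(self, meta):
        from entroscan.imaging import EntropyMap, WindowGrid

        grid = WindowGrid(
            axial_starts=np.array([0, 10]), lateral_starts=np.array([0, 10]),
            window_samples=(11, 11), frame_shape=(21, 21),
        )
        # centers at 5 and 15 on both axes; midpoint (10, 10) averages to 0.5
        emap = EntropyMap(
            values=np.array([[0.0, 1.0], [1.0, 0.0]]), grid=grid,
            estimator="hist", units="bits",
        )
        full = interpolate_map(emap, (21, 21))
        assert full[10, 10] == pytest.approx(0.5, abs=1e-12)


class TestScanConvert:
    def test_linear_flat_field_preserved(self, meta):
        out = scan_convert(np.full((64, 16), 3.0), meta)
        np.testing.assert_allclose(out, 3.0)
        # lateral axis resampled to square pixels: (15 * 0.3 mm) / dps + 1
        expected_cols = round(15 * meta.scanline_pitch / meta.depth_per_sample_mm) + 1
        assert out.shape == (64, expected_cols)

    def test_convex_round_trip_at_ray_depth_coordinates(self):
        meta = AcquisitionMeta(
            sampling_frequency=12e6, center_frequency=3e6, pulse_length=2.3,
            geometry="convex", scanline_pitch=1.0, convex_radius=40.0,
            sector_angle=60.0,
        )
        rng = np.random.default_rng(3)
        img = rng.normal(size=(128, 61))
        # smooth the image so bilinear resampling error is small
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, 3.0)
        out = scan_convert(img, meta)
        dps = meta.depth_per_sample_mm
        half = np.deg2rad(30.0)
        r_grid = 40.0 + np.arange(128) * dps
        x_max = r_grid[-1] * np.sin(half)
        z_min = 40.0 * np.cos(half)
        # sample interior rays/depths, map to display pixels, compare
        for i in (30, 64, 100):
            for j in (10, 30, 50):
                theta = np.deg2rad(-30.0 + j * 1.0)
                x = r_grid[i] * np.sin(theta)
                z = r_grid[i] * np.cos(theta)
                col = (x + x_max) / dps
                row = (z - z_min) / dps
                ri, ci = int(round(row)), int(round(col))
                if 0 <= ri < out.shape[0] and 0 <= ci < out.shape[1]:
                    if np.isfinite(out[ri, ci]):
                        assert out[ri, ci] == pytest.approx(img[i, j], abs=0.05)

    def test_convex_flat_field_constant_inside_nan_outside(self):
        meta = AcquisitionMeta(
            sampling_frequency=12e6, center_frequency=3e6, pulse_length=2.3,
            geometry="convex", scanline_pitch=1.0, convex_radius=30.0,
            sector_angle=45.0,
        )
        out = scan_convert(np.full((64, 46), 1.5), meta)
        inside = out[np.isfinite(out)]
        assert inside.size > 0
        np.testing.assert_allclose(inside, 1.5, atol=1e-9)
        assert np.isnan(out).any()  # sector corners are sentinel


class TestRoiStats:
    def test_direct_arithmetic_example(self):
        img = np.zeros((3, 3))
        img[0, 0], img[1, 1], img[2, 2] = 2.0, 5.0, 9.0
        mask = np.eye(3, dtype=bool)
        stats = roi_stats(img, mask)
        assert stats.mean == pytest.approx(16.0 / 3.0)
        assert stats.dynamic_range == pytest.approx(7.0)

    def test_constant_image_has_zero_dynamic_range(self):
        stats = roi_stats(np.full((5, 5), 1.25), np.ones((5, 5), dtype=bool))
        assert stats.dynamic_range == 0.0 and stats.mean == 1.25

    def test_full_mask_equals_global_aggregate(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(20, 20))
        stats = roi_stats(img, np.ones_like(img, dtype=bool))
        assert stats.mean == pytest.approx(img.mean())
        assert stats.emax == img.max() and stats.emin == img.min()

    def test_sentinel_pixels_excluded(self):
        img = np.array([[1.0, np.nan], [3.0, 5.0]])
        stats = roi_stats(img, np.ones((2, 2), dtype=bool))
        assert stats.mean == pytest.approx(3.0)

    def test_empty_intersection_rejected(self):
        img = np.full((4, 4), np.nan)
        with pytest.raises(EntroscanError, match="ROI outside image"):
            roi_stats(img, np.ones((4, 4), dtype=bool))


class TestColorize:
    def test_nan_becomes_transparent(self):
        img = np.array([[0.0, 1.0], [np.nan, 0.5]])
        rgba = colorize(img)
        assert rgba.shape == (2, 2, 4)
        assert rgba[1, 0, 3] == 0 and rgba[0, 0, 3] == 255
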