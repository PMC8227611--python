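import numpy as np
import pytest

from lenscat.errors import ParameterError, SegmentationError
from lenscat.io_formats import GreyImage
from lenscat.segmentation import (
    CircleROI,
    fit_circle,
    largest_component,
    rasterize_circle,
    segment_lens,
    smooth_image,
    threshold_foreground,
)
from lenscat.synthetic import SyntheticLensConfig, disc_mask, simulate_lens_image

from conftest import QUARTER_SIGMA


def _full_image(value, shape=(64, 64)):
    return GreyImage(pixels=np.full(shape, value, dtype=np.uint8))


class TestSmoothImage:
    def test_constant_image_is_fixed_point(self, flat_image):
        out = smooth_image(flat_image(value=42, shape=(32, 32)), sigma=3.0)
        assert np.allclose(out, 42.0)

    def test_interior_impulse_preserves_mass(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[32, 32] = 200
        out = smooth_image(GreyImage(pixels=px), sigma=2.0)
        assert abs(out.sum() - 200.0) < 1e-6

    def test_disc_brighter_than_corners_after_smoothing(self, quarter_cfg):
        img, _ = simulate_lens_image(quarter_cfg(), "before")
        out = smooth_image(img, sigma=5.0)
        corners = [out[0, 0], out[0, -1], out[-1, 0], out[-1, -1]]
        assert out[135, 240] > max(corners)

    def test_nonpositive_sigma_rejected(self, flat_image):
        with pytest.raises(ParameterError):
            smooth_image(flat_image(), sigma=0.0)


class TestThresholdForeground:
    @pytest.mark.parametrize("rule", ["otsu", "otsu-log"])
    def test_bimodal_separation_exact(self, rule):
        grid = np.full((40, 40), 2.0)
        disc = rasterize_circle((40, 40), CircleROI(20, 20, 10))
        grid[disc] = 40.0
        binary, value = threshold_foreground(grid, rule=rule)
        assert np.array_equal(binary, disc)
        assert 2.0 <= value < 40.0

    def test_fixed_threshold(self):
        grid = np.where(np.arange(400).reshape(20, 20) % 2 == 0, 5.0, 15.0)
        binary, value = threshold_foreground(grid, rule="fixed:10")
        assert value == 10.0
        assert np.array_equal(binary, grid > 10)

    def test_constant_grid_otsu_degenerate(self):
        with pytest.raises(SegmentationError, match="degenerate histogram"):
            threshold_foreground(np.full((20, 20), 3.0), rule="otsu")

    def test_unknown_rule(self):
        with pytest.raises(ParameterError):
            threshold_foreground(np.zeros((20, 20)), rule="magic")


class TestLargestComponent:
    def test_largest_blob_wins(self):
        grid = np.zeros((30, 30), dtype=bool)
        grid[2:12, 2:7] = True  # 50 px
        grid[20:21, 20:23] = True  # 3 px
        out = largest_component(grid)
        assert out[5, 5] and not out[20, 21]
        assert out.sum() == 50

    def test_single_pixel_identity(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[7, 9] = True
        assert np.array_equal(largest_component(grid), grid)

    def test_equal_blobs_tie_break_left(self):
        grid = np.zeros((20, 40), dtype=bool)
        grid[5:10, 2:4] = True  # left 10 px
        grid[5:10, 30:32] = True  # right 10 px
        out = largest_component(grid)
        assert out[7, 2] and not out[7, 30]

    def test_all_false_errors(self):
        with pytest.raises(SegmentationError, match="no foreground"):
            largest_component(np.zeros((20, 20), dtype=bool))

    def test_diagonal_pixels_are_one_component(self):
        grid = np.zeros((20, 20), dtype=bool)
        for i in range(5, 15):
            grid[i, i] = True
        out = largest_component(grid)
        assert out.sum() == 10


class TestFitCircle:
    def test_full_resolution_disc_recovery(self):
        # brute-force rasterization at acquisition scale
        roi_true = CircleROI(960.0, 540.0, 300.0)
        disc = rasterize_circle((1080, 1920), roi_true)
        roi = fit_circle(disc)
        assert abs(roi.center_x - 960.0) <= 2.0
        assert abs(roi.center_y - 540.0) <= 2.0
        assert abs(roi.radius - 300.0) / 300.0 <= 0.02

    def test_centroid_of_symmetric_square(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[0:5, 0:5] = True
        roi = fit_circle(grid)
        assert roi.center_x == pytest.approx(2.0)
        assert roi.center_y == pytest.approx(2.0)

    def test_too_small_component_errors(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[0:3, 0:3] = True  # 9 px < 10
        with pytest.raises(SegmentationError, match="component too small"):
            fit_circle(grid)

    def test_radius_robust_to_radial_spikes(self):
        # acquisition-scale disc (r=300) plus 12 thin outward spikes of
        # length 40 px: percentile rule must track the rim, not the tips
        shape = (800, 800)
        disc = rasterize_circle(shape, CircleROI(400, 400, 300))
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        dx, dy = cols - 400.0, rows - 400.0
        dist = np.hypot(dx, dy)
        ang = np.arctan2(dy, dx)
        spoke = np.remainder(ang, 2 * np.pi / 12)
        near = np.minimum(spoke, 2 * np.pi / 12 - spoke) <= np.deg2rad(0.2)
        spikes = near & (dist > 300) & (dist <= 340)
        assert spikes.sum() > 100  # spikes actually present
        roi = fit_circle(disc | spikes)
        assert abs(roi.radius - 300.0) / 300.0 <= 0.05


class TestSegmentLens:
    def test_noise_free_mask_area_matches_disc(self, quarter_cfg):
        cfg = quarter_cfg()
        img, _ = simulate_lens_image(cfg, "before")
        mask = segment_lens(img, sigma=QUARTER_SIGMA)
        analytic = np.pi * cfg.radius**2
        assert abs(mask.mask.sum() - analytic) / analytic <= 0.03

    def test_all_zero_image_errors(self):
        img = GreyImage(pixels=np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(SegmentationError, match="no foreground|degenerate"):
            segment_lens(img, sigma=2.0)

    def test_center_stable_under_noise_reseeding(self, quarter_cfg):
        centers = []
        for seed in range(1, 6):
            img, _ = simulate_lens_image(quarter_cfg(seed=seed, noise_sd=3.0), "before")
            mask = segment_lens(img, sigma=QUARTER_SIGMA)
            centers.append((mask.roi.center_x, mask.roi.center_y))
        for ax, ay in centers:
            for bx, by in centers:
                assert np.hypot(ax - bx, ay - by) <= 3.0

    def test_deterministic(self, quarter_cfg):
        img, _ = simulate_lens_image(quarter_cfg(seed=3, noise_sd=4.0), "before")
        m1 = segment_lens(img, sigma=QUARTER_SIGMA)
        m2 = segment_lens(img, sigma=QUARTER_SIGMA)
        assert np.array_equal(m1.mask, m2.mask)
        assert m1.roi == m2.roi

    def test_center_robust_to_uniform_brightening(self, quarter_cfg):
        cfg = quarter_cfg()
        img, _ = simulate_lens_image(cfg, "before")
        base = segment_lens(img, sigma=QUARTER_SIGMA)
        for k in (10, 30, 50):
            brightened = GreyImage(
                pixels=np.clip(img.pixels.astype(int) + k, 0, 255).astype(np.uint8)
            )
            m = segment_lens(brightened, sigma=QUARTER_SIGMA)
            shift = np.hypot(m.roi.center_x - base.roi.center_x, m.roi.center_y - base.roi.center_y)
            assert shift <= 2.0

    def test_mask_equals_analytic_disc_up_to_boundary_band(self, quarter_cfg):
        cfg = quarter_cfg()
        img, _ = simulate_lens_image(cfg, "before")
        mask = segment_lens(img, sigma=QUARTER_SIGMA).mask
        truth = disc_mask(cfg)
        diff_rows, diff_cols = np.nonzero(mask ^ truth)
        if diff_rows.size:
            cx, cy = cfg.center
            dist = np.hypot(diff_cols - cx, diff_rows - cy)
            assert np.max(np.abs(dist - cfg.radius)) <= 1.0

    def test_mask_is_rasterization_of_roi(self, quarter_cfg):
        img, _ = simulate_lens_image(quarter_cfg(seed=5, noise_sd=3.0), "before")
        m = segment_lens(img, sigma=QUARTER_SIGMA)
        assert np.array_equal(m.mask, rasterize_circle(img.pixels.shape, m.roi))
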