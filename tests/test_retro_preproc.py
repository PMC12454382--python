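import numpy as np
import pytest

from locsgrade.imgcore import NoCircleFoundError, to_gray
from locsgrade.retro_preproc import (CircleRegion, ClusterState,
                                     RetroPreprocConfig,
                                     cluster_fill_bright_spots,
                                     detect_bright_spots, hough_circle,
                                     min_enclosing_circle, segment_eyeball)
from locsgrade.synthgen import RetroSpec, gen_retro

from oracles import min_circle_oracle, yellow_mean_oracle


class TestMinEnclosingCircle:
    def test_single_point(self):
        c = min_enclosing_circle(np.array([[3.0, 4.0]]))
        assert (c.center_x, c.center_y, c.radius) == (3.0, 4.0, 0.0)

    def test_two_points_diameter(self):
        c = min_enclosing_circle(np.array([[0.0, 0.0], [6.0, 8.0]]))
        assert (c.center_x, c.center_y) == pytest.approx((3.0, 4.0))
        assert c.radius == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(15):
            n = rng.integers(3, 30)
            pts = rng.uniform(0, 100, (n, 2))
            c = min_enclosing_circle(pts)
            ox, oy, orad = min_circle_oracle(pts)
            assert c.radius == pytest.approx(orad, abs=1e-6)
            assert (c.center_x, c.center_y) == pytest.approx((ox, oy), abs=1e-5)
            d = np.hypot(pts[:, 0] - c.center_x, pts[:, 1] - c.center_y)
            assert (d <= c.radius + 1e-6).all()

    def test_accepts_binary_image(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[5, 5] = m[5, 15] = m[15, 5] = m[15, 15] = 255
        c = min_enclosing_circle(m)
        assert (c.center_x, c.center_y) == pytest.approx((10.0, 10.0))
        assert c.radius == pytest.approx(np.hypot(5, 5))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            min_enclosing_circle(np.zeros((10, 10), dtype=np.uint8))


class TestDetectBrightSpots:
    def test_no_bright_pixels_empty_mask(self):
        img = np.full((30, 30, 3), 100, dtype=np.uint8)
        mask = detect_bright_spots(img, CircleRegion(15, 15, 12))
        assert not (mask > 0).any()

    def test_threshold_255_always_empty(self):
        img = np.full((20, 20, 3), 255, dtype=np.uint8)
        mask = detect_bright_spots(img, CircleRegion(10, 10, 8), threshold=255)
        assert not (mask > 0).any()

    def test_saturated_patch_dilated_by_one(self):
        img = np.full((40, 40, 3), 100, dtype=np.uint8)
        img[18:21, 18:21] = 255
        region = CircleRegion(20, 20, 15)
        mask = (detect_bright_spots(img, region) > 0)
        patch = np.zeros((40, 40), bool)
        patch[18:21, 18:21] = True
        dil = np.zeros((40, 40), bool)
        dil[17:22, 17:22] = True
        assert (mask & patch).sum() == patch.sum()   # mask covers the patch
        assert not (mask & ~dil).any()               # and at most its halo
        rows, cols = np.nonzero(mask)
        assert (np.hypot(cols - 20, rows - 20) <= 15).all()


class TestClusterFill:
    def _fixture_image(self):
        """Circle of yellow + black pixels with a white patch to fill."""
        rng = np.random.default_rng(11)
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        region = CircleRegion(25, 25, 20)
        inside = region.pixel_mask(img.shape)
        rows, cols = np.nonzero(inside)
        kind = rng.random(len(rows))
        img[rows, cols] = np.where(kind[:, None] < 0.6, (200, 170, 60),
                                   (15, 10, 10))
        img[23:28, 23:28] = (250, 250, 250)
        mask = np.zeros((50, 50), dtype=np.uint8)
        mask[23:28, 23:28] = 255
        return img, region, mask

    def test_exact_three_colors_fill_is_yellow(self):
        img, region, mask = self._fixture_image()
        out = cluster_fill_bright_spots(img, region, mask)
        assert (out[mask > 0] == (200, 170, 60)).all()

    def test_pixels_outside_mask_unchanged(self):
        img, region, mask = self._fixture_image()
        out = cluster_fill_bright_spots(img, region, mask)
        assert (out[mask == 0] == img[mask == 0]).all()

    def test_empty_mask_identity(self, random_rgb):
        img = random_rgb(30, 30)
        out = cluster_fill_bright_spots(img, CircleRegion(15, 15, 10),
                                        np.zeros((30, 30), dtype=np.uint8))
        assert (out == img).all()

    def test_jittered_fill_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        donors = np.vstack([
            rng.normal([200, 170, 60], 6, (180, 3)),
            rng.normal([250, 250, 250], 2, (40, 3)),
            rng.normal([15, 10, 10], 4, (80, 3)),
        ])
        donors = np.clip(np.floor(donors + 0.5), 0, 255)
        state = ClusterState(donors)
        got = np.floor(state.yellow_mean + 0.5)
        assert (got == yellow_mean_oracle(donors)).all()

    def test_degenerate_two_colors_falls_back_to_mean(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        region = CircleRegion(10, 10, 8)
        inside = region.pixel_mask(img.shape)
        img[inside] = (100, 100, 100)
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[9:12, 9:12] = 255
        img[mask > 0] = (255, 255, 255)
        out = cluster_fill_bright_spots(img, region, mask)
        assert (out[mask > 0] == (100, 100, 100)).all()

    def test_matches_scipy_centroid_linkage(self):
        # independent cross-check of the merge loop against scipy's
        # centroid-linkage hierarchy on a well-separated sample
        from scipy.cluster.hierarchy import cut_tree, linkage
        rng = np.random.default_rng(3)
        donors = np.vstack([
            rng.normal([200, 170, 60], 5, (60, 3)),
            rng.normal([250, 250, 250], 2, (30, 3)),
            rng.normal([15, 10, 10], 4, (40, 3)),
        ])
        state = ClusterState(donors)
        Z = linkage(donors, method="centroid")
        ref = cut_tree(Z, n_clusters=3).ravel()
        ours = state.categories
        # same partition up to label permutation
        for lab in range(3):
            members = ours == lab
            assert len(np.unique(ref[members])) == 1


class TestHoughCircle:
    def _render_circle(self, cx, cy, r, size=100, value=200):
        img = np.zeros((size, size), dtype=np.uint8)
        yy, xx = np.mgrid[0:size, 0:size]
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = value
        return img

    def test_recovers_clean_circle(self):
        gray = self._render_circle(40, 40, 20)
        c = hough_circle(gray, (10, 30))
        assert abs(c.center_x - 40) <= 2
        assert abs(c.center_y - 40) <= 2
        assert abs(c.radius - 20) <= 2

    def test_blank_image_raises(self):
        with pytest.raises(NoCircleFoundError):
            hough_circle(np.zeros((50, 50), dtype=np.uint8), (5, 20))

    def test_stronger_circle_wins(self):
        img = self._render_circle(30, 30, 18, size=120)
        # second, smaller circle -> fewer edge votes at its radius
        yy, xx = np.mgrid[0:120, 0:120]
        ring = np.abs(np.hypot(xx - 85, yy - 85) - 12)
        img[(ring < 1.0) & (np.arange(120)[None, :] % 3 == 0)] = 200
        c = hough_circle(img, (10, 25))
        assert np.hypot(c.center_x - 30, c.center_y - 30) <= 3

    def test_bad_radius_range_rejected(self):
        with pytest.raises(ValueError):
            hough_circle(np.zeros((20, 20), dtype=np.uint8), (10, 2000))


class TestSegmentEyeball:
    def test_recovers_known_pupil(self):
        img, _, _, truth = gen_retro(RetroSpec(c_grade=2, p_grade=0, seed=42))
        seg = segment_eyeball(img, RetroPreprocConfig(sample_n=600))
        c = seg.circle_global
        assert abs(c.center_x - truth["pupil_cx"]) <= 3
        assert abs(c.center_y - truth["pupil_cy"]) <= 3
        assert abs(c.radius - truth["pupil_r"]) <= 3

    def test_no_bright_spots_fill_is_identity(self):
        img, _, _, truth = gen_retro(RetroSpec(flash_spot_count=0, seed=9))
        seg = segment_eyeball(img, RetroPreprocConfig(sample_n=600))
        assert not (seg.bright_mask > 0).any()
        assert (seg.filled == img).all()

    def test_deterministic(self):
        img, _, _, _ = gen_retro(RetroSpec(c_grade=1, seed=5))
        cfg = RetroPreprocConfig(sample_n=400)
        a = segment_eyeball(img, cfg)
        b = segment_eyeball(img, cfg)
        assert (a.crop == b.crop).all()
        assert a.circle_global == b.circle_global

    def test_crop_dimensions_match_circle(self):
        img, _, _, _ = gen_retro(RetroSpec(seed=13))
        seg = segment_eyeball(img, RetroPreprocConfig(sample_n=400))
        c = seg.circle_global
        h, w = seg.crop.shape[:2]
        assert h <= int(np.ceil(2 * c.radius)) + 1
        assert w <= int(np.ceil(2 * c.radius)) + 1
        assert h >= int(2 * c.radius) - 1 or c.center_y < c.radius \
            or c.center_y + c.radius > img.shape[0]
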