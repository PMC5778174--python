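"""Feature extraction, NCC pair adjustment, grid augmentation, point fit."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import cellwarp as cw
from cellwarp import points as pm
from cellwarp.grid_transform import sample_bilinear


@pytest.fixture(scope="module")
def white_square():
    img = np.zeros((10, 10))
    img[3:7, 3:7] = 1.0
    return cw.Image2D(img)


class TestExtractFeatures:
    def test_map_returns_square_boundary(self, white_square):
        ps = pm.extract_features(white_square, "map", threshold=0.5,
                                 foreground="bright")
        got = {tuple(p) for p in ps.coordinates.astype(int)}
        interior = {(x, y) for x in (4, 5) for y in (4, 5)}
        square = {(x, y) for x in range(3, 7) for y in range(3, 7)}
        assert got == square - interior

    def test_skeleton_of_thin_line_is_the_line(self):
        img = np.zeros((12, 12))
        img[6, 2:10] = 1.0
        ps = pm.extract_features(cw.Image2D(img), "skeleton", threshold=0.5,
                                 foreground="bright")
        ys = ps.coordinates[:, 1]
        assert len(ps) >= 4
        assert np.all(ys == 6)

    def test_harris_finds_square_corners(self):
        img = np.zeros((24, 24))
        img[8:16, 8:16] = 1.0
        ps = pm.extract_features(cw.Image2D(ndi.gaussian_filter(img, 0.8)),
                                 "harris", harris_min_distance=3)
        corners = np.array([[8, 8], [8, 15], [15, 8], [15, 15]], dtype=float)
        assert len(ps) == 4
        for c in corners:
            assert np.min(np.linalg.norm(ps.coordinates - c, axis=1)) <= 1.5

    def test_edges_trace_the_square(self, white_square):
        ps = pm.extract_features(white_square, "edges", canny_sigma=1.0)
        assert len(ps) > 0

    def test_manual_points_validated(self, white_square):
        ps = pm.extract_features(white_square, "manual",
                                 points=[[2.0, 3.0], [7.5, 8.5]])
        assert len(ps) == 2
        with pytest.raises(ValueError):
            pm.extract_features(white_square, "manual", points=[[20.0, 0.0]])

    def test_empty_foreground_yields_empty_set_not_error(self):
        flat = cw.Image2D(np.full((16, 16), 0.5))
        ps = pm.extract_features(flat, "map", threshold=0.2, foreground="dark")
        assert len(ps) == 0

    def test_extraction_deterministic(self, bending_pair_64):
        fixed, _, _ = bending_pair_64
        a = pm.extract_features(fixed, "map")
        b = pm.extract_features(fixed, "map")
        assert np.array_equal(a.coordinates, b.coordinates)


class TestAdjustPairsNCC:
    def test_integer_translation_recovered_exactly(self, smooth_texture):
        rolled = cw.Image2D(np.roll(smooth_texture.pixels, 3, axis=1))
        pts = np.array([[30.0, 30.0], [50.0, 45.0], [60.0, 62.0]])
        pairs = pm.adjust_pairs_ncc(smooth_texture, rolled,
                                    pm.PointPairs(pts, pts.copy(), np.ones(3)))
        offsets = pairs.moving_points - pairs.fixed_points
        assert np.array_equal(offsets, np.tile([3.0, 0.0], (3, 1)))

    def test_subpixel_translation_within_tenth_of_pixel(self, smooth_texture):
        h, w = smooth_texture.shape
        ys, xs = np.mgrid[0:h, 0:w]
        shifted = ndi.map_coordinates(smooth_texture.pixels,
                                      [ys.ravel(), np.clip(xs - 2.5, 0, w - 1).ravel()],
                                      order=3).reshape(h, w)
        moving = cw.Image2D(np.clip(shifted, 0, 1))
        pts = np.array([[30.0, 30.0], [48.0, 40.0], [60.0, 60.0]])
        pairs = pm.adjust_pairs_ncc(smooth_texture, moving,
                                    pm.PointPairs(pts, pts.copy(), np.ones(3)))
        offsets = pairs.moving_points - pairs.fixed_points
        assert np.abs(offsets[:, 0] - 2.5).max() <= 0.1
        assert np.abs(offsets[:, 1]).max() <= 0.1

    def test_aligned_pair_not_moved(self, smooth_texture):
        pts = np.array([[30.0, 30.0], [55.0, 40.0]])
        pairs = pm.adjust_pairs_ncc(smooth_texture, smooth_texture,
                                    pm.PointPairs(pts, pts.copy(), np.ones(2)))
        assert np.array_equal(pairs.moving_points, pts)

    def test_adjustment_never_exceeds_search_bound(self, smooth_texture, rng):
        n = 20
        pts = np.stack([rng.uniform(10, 80, n), rng.uniform(10, 80, n)], axis=1)
        noisy = cw.Image2D(np.clip(
            smooth_texture.pixels + rng.normal(0, 0.2, smooth_texture.shape), 0, 1))
        pairs = pm.adjust_pairs_ncc(smooth_texture, noisy,
                                    pm.PointPairs(pts, pts.copy(), np.ones(n)),
                                    search=4, accept_threshold=0.0)
        moved = np.abs(pairs.moving_points - np.round(pairs.fixed_points))
        assert np.all(moved <= 4.5 + 1e-9)

    def test_zero_variance_patch_dropped_with_reason(self):
        flat = cw.Image2D(np.full((32, 32), 0.5))
        pts = np.array([[16.0, 16.0]])
        pairs = pm.adjust_pairs_ncc(flat, flat,
                                    pm.PointPairs(pts, pts.copy(), np.ones(1)))
        assert len(pairs) == 0
        assert "zero-variance" in pairs.dropped[0][1]


class TestAugmentWithGrid:
    def test_too_few_pairs_rejected_with_advice(self):
        pts = np.array([[1.0, 1.0], [5.0, 5.0]])
        pairs = pm.PointPairs(pts, pts + 1.0, np.ones(2))
        with pytest.raises(ValueError, match="intensity-based"):
            pm.augment_with_grid(pairs, (32, 32), 8.0)

    def test_identity_correspondence_maps_grid_nodes_identically(self):
        pts = np.array([[4.0, 4.0], [20.0, 6.0], [10.0, 25.0], [28.0, 28.0]])
        pairs = pm.PointPairs(pts, pts.copy(), np.ones(4))
        aug = pm.augment_with_grid(pairs, (32, 32), 8.0)
        assert len(aug.fixed_points) == len(aug.moving_points)
        grid_f = aug.fixed_points[4:]
        grid_m = aug.moving_points[4:]
        assert np.allclose(grid_f, grid_m, atol=1e-9)

    def test_pure_translation_propagates_to_grid_nodes(self):
        t = np.array([2.0, -1.5])
        pts = np.array([[4.0, 4.0], [20.0, 6.0], [10.0, 25.0]])
        pairs = pm.PointPairs(pts, pts + t, np.ones(3))
        aug = pm.augment_with_grid(pairs, (32, 32), 8.0)
        shift = aug.moving_points - aug.fixed_points
        assert np.allclose(shift, t, atol=1e-9)

    def test_three_noncollinear_pairs_define_exact_affine(self):
        a = np.array([[1.05, 0.02], [-0.01, 0.98]])
        b = np.array([1.0, -2.0])
        pts = np.array([[4.0, 4.0], [24.0, 6.0], [8.0, 26.0]])
        pairs = pm.PointPairs(pts, pts @ a.T + b, np.ones(3))
        aug = pm.augment_with_grid(pairs, (32, 32), 8.0)
        expected = aug.fixed_points @ a.T + b
        assert np.allclose(aug.moving_points, expected, atol=1e-8)


class TestRegisterPoints:
    def test_constant_displacement_fitted_exactly(self):
        t = np.array([1.5, -0.75])
        gx, gy = np.meshgrid(np.arange(4, 64, 8), np.arange(4, 64, 8))
        pts = np.stack([gx.ravel().astype(float), gy.ravel().astype(float)], axis=1)
        aug = pm.AugmentedGrid(pts, pts + t, 8.0, n_features=len(pts))
        transform = pm.register_points(aug, (64, 64), 8.0)
        field = cw.evaluate_local_field(transform.local, (64, 64))
        assert np.abs(field.u_x - t[0]).max() < 1e-6
        assert np.abs(field.u_y - t[1]).max() < 1e-6

    def test_smooth_field_sampled_on_grid_recovered(self, bending_pair_64):
        _, _, truth = bending_pair_64
        gx, gy = np.meshgrid(np.arange(2, 64, 4), np.arange(2, 64, 4))
        pts = np.stack([gx.ravel().astype(float), gy.ravel().astype(float)], axis=1)
        ux = sample_bilinear(truth.u_x, pts[:, 0], pts[:, 1])
        uy = sample_bilinear(truth.u_y, pts[:, 0], pts[:, 1])
        aug = pm.AugmentedGrid(pts, pts + np.stack([ux, uy], axis=1), 4.0,
                               n_features=len(pts))
        transform = pm.register_points(aug, (64, 64), 8.0)
        field = cw.evaluate_local_field(transform.local, (64, 64))
        inner = slice(8, 56)
        rmse = np.sqrt(np.mean(
            (field.u_x[inner, inner] - truth.u_x[inner, inner]) ** 2
            + (field.u_y[inner, inner] - truth.u_y[inner, inner]) ** 2))
        assert rmse < 0.2

    def test_residual_decreases_monotonically_across_levels(self, bending_pair_64):
        _, _, truth = bending_pair_64
        gx, gy = np.meshgrid(np.arange(2, 64, 4), np.arange(2, 64, 4))
        pts = np.stack([gx.ravel().astype(float), gy.ravel().astype(float)], axis=1)
        ux = sample_bilinear(truth.u_x, pts[:, 0], pts[:, 1])
        uy = sample_bilinear(truth.u_y, pts[:, 0], pts[:, 1])
        aug = pm.AugmentedGrid(pts, pts + np.stack([ux, uy], axis=1), 4.0,
                               n_features=len(pts))
        transform = pm.register_points(aug, (64, 64), 8.0)
        hist = np.array(transform.residual_history)
        assert np.all(np.diff(hist) <= 1e-12)
        assert hist[-1] < hist[0]

    def test_single_outlier_perturbs_only_nearby_cells(self):
        t = np.array([1.0, 0.0])
        gx, gy = np.meshgrid(np.arange(4, 64, 4), np.arange(4, 64, 4))
        pts = np.stack([gx.ravel().astype(float), gy.ravel().astype(float)], axis=1)
        moving = pts + t
        center = np.argmin(np.linalg.norm(pts - [32, 32], axis=1))
        moving[center] += [3.0, 0.0]
        aug = pm.AugmentedGrid(pts, moving, 4.0, n_features=len(pts))
        transform = pm.register_points(aug, (64, 64), 16.0)
        field = cw.evaluate_local_field(transform.local, (64, 64))
        far = np.zeros((64, 64), dtype=bool)
        far[:, :] = True
        ys, xs = np.mgrid[0:64, 0:64]
        far &= np.hypot(xs - 32, ys - 32) > 32  # beyond 2 cells of 16 px
        assert np.abs(field.u_x[far] - 1.0).max() < 0.1

    def test_too_few_pairs_rejected(self):
        pts = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        aug = pm.AugmentedGrid(pts, pts, 8.0, n_features=3)
        with pytest.raises(ValueError):
            pm.register_points(aug, (32, 32), 8.0)
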