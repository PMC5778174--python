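"""Cubic B-spline FFD: bases, lattice construction, evaluation, warping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellwarp as cw
from cellwarp.grid_transform import evaluate_local_field, sample_bilinear


class TestBasis:
    @pytest.mark.parametrize("l,u,expected", [
        (0, 0.0, 1 / 6),
        (1, 0.0, 4 / 6),
        (2, 0.0, 1 / 6),
        (3, 0.0, 0.0),
        (0, 0.5, 0.125 / 6),
        (3, 0.5, 0.125 / 6),
    ])
    def test_known_values(self, l, u, expected):
        assert cw.basis(l, u) == pytest.approx(expected, abs=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    def test_partition_of_unity_and_nonnegativity(self, u):
        vals = [cw.basis(l, u) for l in range(4)]
        assert all(v >= 0 for v in vals)
        assert sum(vals) == pytest.approx(1.0, abs=1e-12)

    def test_partition_of_unity_dense_grid(self):
        u = np.linspace(0, 1, 1000, endpoint=False)
        total = sum(cw.basis(l, u) for l in range(4))
        assert np.abs(total - 1).max() < 1e-12

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            cw.basis(4, 0.5)

    def test_derivatives_match_finite_differences(self):
        u = np.linspace(0.05, 0.95, 19)
        h = 1e-6
        for l in range(4):
            d1 = (cw.basis(l, u + h) - cw.basis(l, u - h)) / (2 * h)
            assert np.abs(d1 - cw.basis(l, u, order=1)).max() < 1e-8
            d2 = (cw.basis(l, u + h, order=1) - cw.basis(l, u - h, order=1)) / (2 * h)
            assert np.abs(d2 - cw.basis(l, u, order=2)).max() < 1e-8


class TestBuildGrid:
    def test_lattice_count_includes_margin_ring(self):
        grid = cw.build_grid((64, 64), 16)
        assert grid.extent == (7, 7)
        assert np.all(grid.displacements == 0.0)

    def test_every_pixel_has_full_support(self):
        # evaluating at the extreme corners must not raise
        grid = cw.build_grid((50, 70), 9)
        out = cw.evaluate_local(grid, [[0.0, 0.0], [69.0, 49.0]])
        assert out.shape == (2, 2)

    def test_spacing_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            cw.build_grid((64, 64), 65)

    def test_tiny_spacing_rejected(self):
        with pytest.raises(ValueError):
            cw.build_grid((64, 64), 1.0)


class TestEvaluateLocal:
    def test_zero_grid_gives_zero_displacement(self):
        grid = cw.build_grid((32, 32), 8)
        field = evaluate_local_field(grid, (32, 32))
        assert np.all(field.u_x == 0) and np.all(field.u_y == 0)

    def test_constant_control_displacements_reproduced_exactly(self):
        # partition of unity: a constant lattice is a pure translation
        grid = cw.build_grid((32, 32), 8)
        grid.displacements[..., 0] = 2.5
        grid.displacements[..., 1] = -1.25
        field = evaluate_local_field(grid, (32, 32))
        assert np.abs(field.u_x - 2.5).max() < 1e-12
        assert np.abs(field.u_y + 1.25).max() < 1e-12

    def test_single_control_point_weight(self):
        # at a pixel with local parameters u=v=0 the center weight is (4/6)²
        grid = cw.build_grid((64, 64), 16)
        grid.displacements[3, 3, 0] = 1.0  # lattice (2,2) = pixel (32,32) support center
        out = cw.evaluate_local(grid, [[32.0, 32.0]])
        assert out[0, 0] == pytest.approx((4 / 6) ** 2, abs=1e-12)
        assert out[0, 1] == 0.0

    def test_out_of_domain_coordinate_rejected(self):
        grid = cw.build_grid((32, 32), 8)
        with pytest.raises(ValueError):
            cw.evaluate_local(grid, [[-5.0, 0.0]])

    def test_second_derivative_continuous_across_knots(self):
        # C² continuity: the FD second derivative jump across a knot shrinks
        # linearly with the sampling step (only the third derivative jumps)
        r = np.random.default_rng(3)
        grid = cw.build_grid((64, 64), 16)
        grid.displacements[:] = r.uniform(-2, 2, grid.displacements.shape)
        knot_x = 32.0
        jumps = []
        for h in (0.1, 0.05, 0.025):
            def d2(x):
                pts = np.array([[x - h, 20.0], [x, 20.0], [x + h, 20.0]])
                vals = cw.evaluate_local(grid, pts)[:, 0]
                return (vals[0] - 2 * vals[1] + vals[2]) / h**2
            jumps.append(abs(d2(knot_x - 2 * h) - d2(knot_x + 2 * h)))
        assert jumps[2] < jumps[0] + 1e-9
        assert jumps[2] < 0.2


class TestTotalTransform:
    def test_identity_maps_points_to_themselves(self):
        t = cw.Transform2D.identity((64, 64), 16)
        out = cw.total_transform(t, [[10.0, 20.0]])
        assert np.allclose(out, [[10.0, 20.0]])

    def test_affine_translation_adds(self):
        t = cw.Transform2D(cw.AffineParams(np.eye(2), [3.0, 0.0]),
                           cw.build_grid((64, 64), 16))
        out = cw.total_transform(t, [[10.0, 20.0]])
        assert np.allclose(out, [[13.0, 20.0]])

    def test_constant_local_displacement_adds(self):
        t = cw.Transform2D.identity((64, 64), 16)
        t.local.displacements[..., 0] = 1.5
        out = cw.total_transform(t, [[10.0, 20.0], [40.0, 5.0]])
        assert np.allclose(out, [[11.5, 20.0], [41.5, 5.0]])


class TestWarp:
    def test_identity_transform_is_bitwise_identity(self, smooth_texture):
        t = cw.Transform2D.identity(smooth_texture.shape, 8)
        out = cw.warp(smooth_texture, t)
        assert np.array_equal(out.pixels, smooth_texture.pixels)

    def test_backward_convention_shifts_bright_pixel_left(self):
        img = np.zeros((16, 16))
        img[8, 10] = 1.0
        t = cw.Transform2D(cw.AffineParams(np.eye(2), [5.0, 0.0]),
                           cw.build_grid((16, 16), 8))
        out = cw.warp(cw.Image2D(img), t)
        assert out.pixels[8, 5] == 1.0
        assert out.pixels[8, 10] == 0.0

    def test_halfpixel_shift_exact_on_linear_ramp(self):
        ramp = np.tile(np.arange(32, dtype=float) / 31.0, (8, 1))
        t = cw.Transform2D(cw.AffineParams(np.eye(2), [0.5, 0.0]),
                           cw.build_grid((8, 32), 8))
        out = cw.warp(cw.Image2D(ramp), t)
        inner = out.pixels[:, :-1]
        expected = ramp[:, :-1] + 0.5 / 31.0
        assert np.abs(inner - expected).max() < 1e-12


class TestBilinearSampler:
    def test_gradient_matches_finite_differences_at_generic_points(self, rng):
        img = rng.random((24, 24))
        xs = rng.uniform(2.3, 20.7, 40)
        ys = rng.uniform(2.3, 20.7, 40)
        _, gx, gy = sample_bilinear(img, xs, ys, with_gradient=True)
        h = 1e-6
        fx = (sample_bilinear(img, xs + h, ys) - sample_bilinear(img, xs - h, ys)) / (2 * h)
        fy = (sample_bilinear(img, xs, ys + h) - sample_bilinear(img, xs, ys - h)) / (2 * h)
        assert np.abs(gx - fx).max() < 1e-6
        assert np.abs(gy - fy).max() < 1e-6


class TestFitGridToField:
    def test_in_span_field_recovered_exactly(self):
        r = np.random.default_rng(7)
        truth = cw.build_grid((48, 48), 12)
        truth.displacements[:] = r.uniform(-3, 3, truth.displacements.shape)
        dense = evaluate_local_field(truth, (48, 48))
        fitted = cw.fit_grid_to_field(dense, 12)
        refit = evaluate_local_field(fitted, (48, 48))
        assert np.abs(refit.u_x - dense.u_x).max() < 1e-6
        assert np.abs(refit.u_y - dense.u_y).max() < 1e-6
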