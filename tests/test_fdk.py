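import numpy as np
import pytest

from sparsecbct.fdk import (ReconSpec, backproject, fdk_reconstruct,
                            parker_weights, preweight, ramp_filter,
                            ramp_kernel)
from sparsecbct.geometry import (ScanGeometry, generate_view_angles,
                                 subsample_indices)
from sparsecbct.phantoms import GridSpec, MU_WATER


class TestPreweight:
    def test_principal_ray_weight_is_one(self, small_geometry):
        g = small_geometry
        frames = np.ones((1, g.detector_rows, g.detector_cols))
        w = preweight(frames, g)
        r, c = g.detector_rows // 2, g.detector_cols // 2
        # detector centers are half a pixel off the principal ray
        assert w[0, r, c] == pytest.approx(1.0, abs=1e-5)

    def test_corner_weight_below_one(self, small_geometry):
        g = small_geometry
        w = preweight(np.ones((1, g.detector_rows, g.detector_cols)), g)
        assert w[0, 0, 0] < w[0, g.detector_rows // 2, g.detector_cols // 2]

    def test_closed_form_at_u_equal_d(self):
        # a pixel offset u = D from the principal ray weighs 1/sqrt(2)
        g = ScanGeometry(detector_cols=3, detector_rows=1,
                         pixel_pitch_mm=1536.0)
        w = preweight(np.ones((1, 1, 3)), g)
        assert w[0, 0, 0] == pytest.approx(1 / np.sqrt(2))


class TestParkerWeights:
    def test_full_scan_uses_half_weighting(self):
        g = ScanGeometry(arc_span_deg=360).scaled(0.25)
        w = parker_weights(np.arange(0, 360, 10.0), g)
        assert np.all(w == 0.5)

    def test_short_scan_weights_bounded_and_continuous(self):
        g = ScanGeometry(arc_start_deg=260, arc_span_deg=200).scaled(0.25)
        angles = generate_view_angles(g, 400)
        w = parker_weights(angles, g)
        assert np.all((w >= 0) & (w <= 1 + 1e-12))
        # continuity: on a fine beta grid the weight field has no jumps
        from sparsecbct.fdk import parker_weight_function

        delta = np.deg2rad(10.0)
        beta = np.linspace(0, np.pi + 2 * delta, 20001)
        wf = parker_weight_function(beta, np.deg2rad(7.0), delta)
        assert np.abs(np.diff(wf)).max() < 5e-3

    def test_redundancy_sums_to_one_over_ray_table(self):
        from sparsecbct.fdk import parker_weight_function

        delta = np.deg2rad(10.0)
        span = np.pi + 2 * delta
        fan = np.deg2rad(7.5)  # physical fan half-angle <= delta
        beta = np.linspace(0, span, 601)
        gamma = np.linspace(-fan, fan, 101)
        bb, gg = np.meshgrid(beta, gamma, indexing="ij")
        w = parker_weight_function(bb, gg, delta)
        # a ray (beta, gamma) is re-measured at (beta + pi + 2 gamma, -gamma)
        partner_b = bb + np.pi + 2 * gg
        inside = partner_b <= span + 1e-12
        w2 = parker_weight_function(partner_b[inside], -gg[inside], delta)
        assert np.abs(w[inside] + w2 - 1.0).max() < 1e-6

    def test_arc_shorter_than_180_plus_fan_raises(self):
        g = ScanGeometry(arc_start_deg=0, arc_span_deg=170).scaled(0.25)
        with pytest.raises(ValueError, match="arc span"):
            parker_weights(np.arange(0, 170, 5.0), g)


class TestRampFilter:
    def test_constant_row_interior_strongly_suppressed(self):
        # the band-limited kernel suppresses DC: away from the row's two
        # step edges the response is a few percent of the impulse peak
        # (the truncated discrete kernel retains a small DC residual)
        rows = np.full((2, 4, 256), 3.0)
        out = ramp_filter(rows, spacing=1.0)
        peak = ramp_kernel(3, 1.0)[1] * 1.0 * 3.0  # impulse-response scale
        assert np.abs(out[..., 64:192]).max() < 0.05 * peak

    def test_dc_residual_shrinks_with_kernel_length(self):
        sums = [abs(ramp_kernel(2 * n - 1, 1.0).sum()) for n in (32, 256)]
        assert sums[1] < 0.2 * sums[0]

    def test_impulse_reproduces_discrete_ram_lak_kernel(self):
        n = 32
        frames = np.zeros((1, 1, n))
        frames[0, 0, n // 2] = 1.0
        d = 0.7
        out = ramp_filter(frames, spacing=d)
        k = ramp_kernel(2 * n - 1, d)
        expected = k[n - 1 - n // 2: 2 * n - 1 - n // 2] * d
        assert np.allclose(out[0, 0], expected, atol=1e-9)

    def test_shepp_logan_kernel_closed_form(self):
        d = 1.25
        k = ramp_kernel(9, d, "shepp-logan")
        n = np.arange(-4, 5)
        assert np.allclose(k, -2 / (np.pi ** 2 * d ** 2 * (4 * n ** 2 - 1)))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(1, 3, 40))
        b = rng.normal(size=(1, 3, 40))
        assert np.allclose(ramp_filter(a + b, 1.0),
                           ramp_filter(a, 1.0) + ramp_filter(b, 1.0),
                           atol=1e-10)


class TestFdkReconstruct:
    def test_uniform_cylinder_mean_within_three_percent(self, cylinder_stack):
        _, stack = cylinder_stack
        grid = GridSpec.cube(64, 3.125)
        rec = fdk_reconstruct(stack, ReconSpec(grid=grid))
        xs = grid.axis_coords(0)
        r2 = xs[:, None] ** 2 + xs[None, :] ** 2
        mask = (r2 < 40 ** 2)[:, :, None] & \
            (np.abs(grid.axis_coords(2)) < 30)[None, None, :]
        assert rec.voxels[mask].mean() == pytest.approx(MU_WATER, rel=0.03)

    def test_sparse_scheme_mean_matches_full(self, cylinder_stack):
        _, stack = cylinder_stack
        grid = GridSpec.cube(64, 3.125)
        xs = grid.axis_coords(0)
        r2 = xs[:, None] ** 2 + xs[None, :] ** 2
        mask = (r2 < 40 ** 2)[:, :, None] & \
            (np.abs(grid.axis_coords(2)) < 30)[None, None, :]
        means = {}
        for n in (1, 6):
            spec = ReconSpec(grid=grid,
                             subsample=subsample_indices(stack.n_views, n))
            means[n] = fdk_reconstruct(stack, spec).voxels[mask].mean()
        assert means[6] == pytest.approx(means[1], rel=0.03)

    def test_single_view_is_finite(self, cylinder_stack):
        _, stack = cylinder_stack
        spec = ReconSpec(grid=GridSpec.cube(32, 6.0),
                         subsample=subsample_indices(stack.n_views,
                                                     stack.n_views))
        rec = fdk_reconstruct(stack, spec)
        assert np.all(np.isfinite(rec.voxels))

    def test_determinism(self, cylinder_stack):
        _, stack = cylinder_stack
        spec = ReconSpec(grid=GridSpec.cube(32, 6.0))
        a = fdk_reconstruct(stack, spec)
        b = fdk_reconstruct(stack, spec)
        assert np.array_equal(a.voxels, b.voxels)

    def test_empty_subsample_rejected(self, cylinder_stack):
        _, stack = cylinder_stack
        from sparsecbct.geometry import SubsampleScheme

        empty = SubsampleScheme(9999, "XVI-1/9999", ())
        with pytest.raises(ValueError):
            fdk_reconstruct(stack, ReconSpec(subsample=empty))

    def test_short_scan_reconstruction_of_off_center_sphere(self):
        from sparsecbct.phantoms import PhantomSpec, Primitive
        from sparsecbct.projector import forward_project_analytic

        geom = ScanGeometry(arc_start_deg=260, arc_span_deg=200).scaled(0.25)
        spec = PhantomSpec("s", [
            Primitive("ellipsoid", (15, -10, 0), (40, 40, 40), MU_WATER)
        ], GridSpec.cube(64, 3.0))
        stack = forward_project_analytic(
            spec, geom, generate_view_angles(geom, 220))
        rec = fdk_reconstruct(stack, ReconSpec(grid=GridSpec.cube(64, 3.0)))
        grid = rec.grid
        gx, gy, gz = np.meshgrid(grid.axis_coords(0), grid.axis_coords(1),
                                 grid.axis_coords(2), indexing="ij")
        inside = ((gx - 15) ** 2 + (gy + 10) ** 2 + gz ** 2) < 20 ** 2
        assert rec.voxels[inside].mean() == pytest.approx(MU_WATER, rel=0.05)
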