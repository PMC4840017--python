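"""Contrast-image interpolation: 2D linear + smoothing, 3D spherical splines."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from nirstopo import (
    ContrastImage,
    GridInterpolator,
    ScalpGrid2D,
    SphericalSplineInterpolator,
    interp2d_linear,
    make_canonical_mesh,
    make_search_mask,
    smooth_gaussian,
    spline_g,
)
from nirstopo.interp import read_image, write_image, write_surface


@pytest.fixture
def square_channels():
    """Nine channels on a regular 3x3 grid spanning +-60 mm."""
    g = np.linspace(-60.0, 60.0, 3)
    xx, yy = np.meshgrid(g, g)
    return np.column_stack([xx.ravel(), yy.ravel()])


class TestLinearInterp:
    def test_constant_field_reproduced(self, square_channels):
        img = interp2d_linear(square_channels, np.full(9, 5.0), ScalpGrid2D(n=32, extent=100.0))
        np.testing.assert_allclose(img.values[img.mask], 5.0, atol=1e-9)

    def test_affine_field_exact(self, square_channels):
        a, b, c = 0.03, -0.02, 1.5
        w = a * square_channels[:, 0] + b * square_channels[:, 1] + c
        grid = ScalpGrid2D(n=64, extent=100.0)
        img = interp2d_linear(square_channels, w, grid)
        xx, yy = grid.pixel_centers()
        expected = a * xx + b * yy + c
        np.testing.assert_allclose(img.values[img.mask], expected[img.mask], atol=1e-9)

    def test_pixel_at_channel_equals_channel_value(self, rng):
        grid = ScalpGrid2D(n=32, extent=96.0)  # pixel size 6 mm, centers at +-3,9,...
        xx, yy = grid.pixel_centers()
        chan = np.array([[xx[8, 8], yy[8, 8]], [xx[20, 10], yy[20, 10]], [xx[10, 22], yy[10, 22]], [xx[25, 25], yy[25, 25]]])
        w = rng.normal(size=4)
        img = interp2d_linear(chan, w, grid)
        assert img.values[8, 8] == pytest.approx(w[0], abs=1e-9)
        assert img.values[20, 10] == pytest.approx(w[1], abs=1e-9)

    def test_outside_hull_masked(self, square_channels):
        img = interp2d_linear(square_channels, np.ones(9), ScalpGrid2D(n=64, extent=130.0))
        xx, yy = img.grid.pixel_centers()
        outside = (np.abs(xx) > 61) | (np.abs(yy) > 61)
        assert not img.mask[outside].any()
        assert np.isnan(img.values[outside]).all()

    def test_collinear_channels_rejected(self):
        chan = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="triangulation"):
            interp2d_linear(chan, np.ones(5), ScalpGrid2D(n=32, extent=100.0))

    def test_linear_operator_in_contrast(self, square_channels, rng):
        grid = ScalpGrid2D(n=32, extent=100.0)
        gi = GridInterpolator(grid).fit(square_channels)
        w1, w2 = rng.normal(size=9), rng.normal(size=9)
        a, b = 1.7, -0.4
        combo = gi.transform(a * w1 + b * w2).values
        lin = a * gi.transform(w1).values + b * gi.transform(w2).values
        m = np.isfinite(combo)
        np.testing.assert_allclose(combo[m], lin[m], atol=1e-9)

    def test_values_within_data_range(self, square_channels, rng):
        w = rng.normal(size=9)
        img = interp2d_linear(square_channels, w, ScalpGrid2D(n=64, extent=100.0))
        vals = img.values[img.mask]
        assert vals.min() >= w.min() - 1e-9 and vals.max() <= w.max() + 1e-9


class TestSmoothing:
    def test_constant_preserved_inside_mask(self, square_channels):
        img = interp2d_linear(square_channels, np.full(9, 2.5), ScalpGrid2D(n=64, extent=100.0))
        sm = smooth_gaussian(img, fwhm=14.0)
        np.testing.assert_allclose(sm.values[sm.mask], 2.5, atol=1e-8)

    def test_impulse_matches_sampled_gaussian(self):
        grid = ScalpGrid2D(n=64, extent=64.0, mask=np.ones((64, 64), bool))
        vals = np.zeros((64, 64))
        vals[32, 32] = 1.0
        img = ContrastImage(space="grid2d", values=vals, mask=grid.mask, grid=grid)
        fwhm = 14.0
        sm = smooth_gaussian(img, fwhm)
        sigma_px = fwhm / (2 * np.sqrt(2 * np.log(2))) / grid.pixel_size
        assert sigma_px * grid.pixel_size == pytest.approx(5.9447, abs=1e-3)
        oracle = gaussian_filter(vals, sigma_px, mode="constant")
        np.testing.assert_allclose(sm.values, oracle, atol=1e-6)
        assert sm.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_positive_fwhm_required(self, square_channels):
        img = interp2d_linear(square_channels, np.ones(9), ScalpGrid2D(n=32, extent=100.0))
        with pytest.raises(ValueError, match="fwhm"):
            smooth_gaussian(img, 0.0)


class TestSplineKernel:
    def test_truncation_tolerance_controls_error(self):
        x = np.linspace(-1, 1, 21)
        a = spline_g(x, m=4, tol=1e-12)
        b = spline_g(x, m=4, tol=1e-15)
        assert np.max(np.abs(a - b)) < 1e-11

    def test_value_at_one_matches_500_term_sum(self):
        n = np.arange(1, 501, dtype=float)
        oracle = np.sum((2 * n + 1) / (n * (n + 1)) ** 4) / (4 * np.pi)
        assert spline_g(1.0, m=4, tol=1e-16) == pytest.approx(oracle, abs=1e-12)

    def test_value_at_minus_one_alternating_series(self):
        n = np.arange(1, 501, dtype=float)
        oracle = np.sum((-1.0) ** n * (2 * n + 1) / (n * (n + 1)) ** 4) / (4 * np.pi)
        assert spline_g(-1.0, m=4, tol=1e-16) == pytest.approx(oracle, abs=1e-12)

    def test_low_order_diverges(self):
        with pytest.raises(ValueError, match="m"):
            spline_g(0.5, m=1)


class TestSphericalSpline:
    def test_constant_data_gives_offset_only(self, probe_geometry):
        dirs, *_ = probe_geometry
        model = SphericalSplineInterpolator().fit(dirs, np.full(len(dirs), 3.2))
        assert model.k0_ == pytest.approx(3.2, abs=1e-8)
        np.testing.assert_allclose(model.k_, 0.0, atol=1e-8)
        assert model.k_.sum() == pytest.approx(0.0, abs=1e-10)

    def test_reproduces_data_at_channels(self, rng):
        dirs = rng.normal(size=(10, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = rng.normal(size=10)
        model = SphericalSplineInterpolator().fit(dirs, w)
        np.testing.assert_allclose(model.predict(dirs), w, atol=1e-8)
        # zero-sum constraint, to roundoff of the coefficient scale
        tol = 1e-10 * max(1.0, np.abs(model.k_).max())
        assert abs(model.k_.sum()) < tol

    def test_coefficients_match_dense_solve(self, rng):
        dirs = rng.normal(size=(8, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = rng.normal(size=8)
        model = SphericalSplineInterpolator().fit(dirs, w)
        # independent assembly + solve of the augmented system
        G = spline_g(np.clip(dirs @ dirs.T, -1, 1), 4, 1e-10)
        A = np.block([[G, np.ones((8, 1))], [np.ones((1, 8)), np.zeros((1, 1))]])
        sol = np.linalg.lstsq(A, np.concatenate([w, [0.0]]), rcond=None)[0]
        np.testing.assert_allclose(model.k_, sol[:8], atol=1e-9)
        assert model.k0_ == pytest.approx(sol[8], abs=1e-9)

    def test_zero_coefficients_constant_prediction(self, probe_geometry, rng):
        dirs, *_ = probe_geometry
        model = SphericalSplineInterpolator().fit(dirs, rng.normal(size=52))
        model.k_ = np.zeros(52)
        model.k0_ = 1.23
        pts = rng.normal(size=(20, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        np.testing.assert_allclose(model.predict(pts), 1.23, atol=1e-14)

    def test_rotation_equivariance(self, rng):
        dirs = rng.normal(size=(12, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = rng.normal(size=12)
        pts = rng.normal(size=(30, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        R = Rotation.random(random_state=7).as_matrix()
        base = SphericalSplineInterpolator().fit(dirs, w).predict(pts)
        rot = SphericalSplineInterpolator().fit(dirs @ R.T, w).predict(pts @ R.T)
        np.testing.assert_allclose(rot, base, atol=1e-9)

    def test_duplicate_channels_named(self, rng):
        dirs = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]])
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            SphericalSplineInterpolator().fit(dirs, np.arange(4.0))

    def test_non_unit_points_rejected(self, probe_geometry, rng):
        dirs, *_ = probe_geometry
        model = SphericalSplineInterpolator().fit(dirs, rng.normal(size=52))
        with pytest.raises(ValueError, match="unit"):
            model.predict(np.array([[2.0, 0.0, 0.0]]))

    def test_interpolant_linear_in_data(self, probe_geometry, rng):
        dirs, *_ = probe_geometry
        pts = rng.normal(size=(15, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        w1, w2 = rng.normal(size=52), rng.normal(size=52)
        f = lambda w: SphericalSplineInterpolator().fit(dirs, w).predict(pts)
        np.testing.assert_allclose(
            f(2.0 * w1 - 0.5 * w2), 2.0 * f(w1) - 0.5 * f(w2), atol=1e-9
        )


class TestCrossRepresentation:
    def test_grid_and_mesh_images_agree_on_smooth_field(self, probe_geometry):
        dirs, center, radius, xy = probe_geometry
        field = lambda d: 2.0 * d[:, 0] + 1.0 * d[:, 2] - 0.5 * d[:, 1]
        w = field(dirs)
        mesh = make_canonical_mesh(3, radius=radius)
        mmask = make_search_mask(mesh, dirs, 25.0)
        spl = SphericalSplineInterpolator().fit(dirs, w)
        img3 = spl.to_mesh_image(mesh, mmask)
        grid = ScalpGrid2D(n=64, extent=float(np.abs(xy).max() + 10))
        img2 = smooth_gaussian(interp2d_linear(xy, w, grid), 14.0)
        # evaluate both at masked mesh vertices projected to the disc
        from nirstopo import project_channels_disc

        vxy = project_channels_disc(mesh.vertices[mmask], radius)
        ii = np.clip(((vxy[:, 0] + grid.extent) / grid.pixel_size).astype(int), 0, 63)
        jj = np.clip(((vxy[:, 1] + grid.extent) / grid.pixel_size).astype(int), 0, 63)
        g_vals = img2.values[ii, jj]
        m_vals = img3.values[mmask]
        ok = np.isfinite(g_vals)
        r = np.corrcoef(g_vals[ok], m_vals[ok])[0, 1]
        assert r > 0.9


class TestSerialization:
    def test_grid_roundtrip_bitwise(self, square_channels, rng, tmp_path):
        img = interp2d_linear(square_channels, rng.normal(size=9), ScalpGrid2D(n=32, extent=100.0))
        p = tmp_path / "sub-01_interference_grid2d.nii"
        write_image(img, p)
        back = read_image(p)
        np.testing.assert_array_equal(back.values[back.mask], img.values[img.mask])
        np.testing.assert_array_equal(back.mask, img.mask)
        assert back.grid.pixel_size == pytest.approx(img.grid.pixel_size, abs=1e-9)

    def test_mesh_roundtrip(self, coarse_mesh, rng, tmp_path):
        mask = np.zeros(coarse_mesh.n_vertices, bool)
        mask[:50] = True
        vals = np.full(coarse_mesh.n_vertices, np.nan)
        vals[mask] = rng.normal(size=50)
        img = ContrastImage(
            space="mesh3d", values=vals, mask=mask, mesh=coarse_mesh, subject_id="sub-07"
        )
        p = tmp_path / "sub-07_interference_mesh3d.gii"
        write_image(img, p)
        back = read_image(p, mesh=coarse_mesh)
        assert back.values.shape[0] == coarse_mesh.n_vertices
        assert back.subject_id == "sub-07"
        np.testing.assert_allclose(back.values[mask], vals[mask], rtol=1e-6)
        np.testing.assert_array_equal(back.mask, mask)

    def test_surface_file_written(self, coarse_mesh, tmp_path):
        import nibabel as nib

        p = tmp_path / "scalp.surf.gii"
        write_surface(coarse_mesh, p)
        g = nib.load(p)
        assert g.darrays[0].data.shape == (coarse_mesh.n_vertices, 3)
        assert g.darrays[1].data.shape == (len(coarse_mesh.faces), 3)

    def test_unsupported_extension(self, square_channels):
        img = interp2d_linear(square_channels, np.ones(9), ScalpGrid2D(n=32, extent=100.0))
        with pytest.raises(ValueError, match="nii"):
            write_image(img, "out.mat")
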