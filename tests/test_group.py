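"""Second-level random effects and random-field-theory inference."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, label
from scipy.stats import t as t_dist

from nirstopo import (
    ContrastImage,
    GroupDesign,
    ScalpGrid2D,
    bonferroni_threshold,
    cluster_inference,
    ec_density,
    estimate_smoothness,
    fit_second_level,
    make_canonical_mesh,
    peak_pvalue,
    rft_peak_threshold,
    run_group_inference,
    stack_contrasts,
)
from nirstopo.group import ReselInfo, _ec_sum


def _grid_image(values, grid, mask=None):
    mask = np.isfinite(values) if mask is None else mask
    return ContrastImage(space="grid2d", values=values, mask=mask, grid=grid)


class TestStack:
    def test_identical_masks(self, rng):
        grid = ScalpGrid2D(n=16, extent=50.0, mask=np.ones((16, 16), bool))
        imgs = [_grid_image(rng.normal(size=(16, 16)), grid) for _ in range(3)]
        W, mask, _ = stack_contrasts(imgs)
        assert W.shape == (3, 256)
        np.testing.assert_array_equal(mask, np.ones((16, 16), bool))

    def test_mask_intersection(self, rng):
        grid = ScalpGrid2D(n=16, extent=50.0, mask=np.ones((16, 16), bool))
        v1 = rng.normal(size=(16, 16))
        v2 = rng.normal(size=(16, 16))
        v2[0:4] = np.nan
        imgs = [_grid_image(v1, grid), _grid_image(v2, grid)]
        _, mask, _ = stack_contrasts(imgs)
        expected = np.isfinite(v1) & np.isfinite(v2)
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() < 256

    def test_single_subject_rejected(self, rng):
        grid = ScalpGrid2D(n=16, extent=50.0)
        with pytest.raises(ValueError, match="2 subjects"):
            stack_contrasts([_grid_image(rng.normal(size=(16, 16)), grid)])

    def test_mixed_spaces_rejected(self, rng, coarse_mesh):
        grid = ScalpGrid2D(n=16, extent=50.0)
        g = _grid_image(rng.normal(size=(16, 16)), grid)
        vals = rng.normal(size=coarse_mesh.n_vertices)
        m = ContrastImage(
            space="mesh3d", values=vals, mask=np.isfinite(vals), mesh=coarse_mesh
        )
        with pytest.raises(ValueError, match="space"):
            stack_contrasts([g, m])


class TestSecondLevel:
    def test_one_sample_dof_21_subjects(self, rng):
        res = fit_second_level(rng.normal(size=(21, 10)), GroupDesign.one_sample(21))
        assert res.dof == 20

    def test_matches_textbook_one_sample_t(self, rng):
        W = rng.normal(size=(8, 50))
        res = fit_second_level(W, GroupDesign.one_sample(8))
        manual = W.mean(axis=0) / (W.std(axis=0, ddof=1) / np.sqrt(8))
        np.testing.assert_allclose(res.T, manual, atol=1e-10)

    def test_zero_variance_flagged_not_crashed(self):
        W = np.tile([[1.0, 2.0]], (5, 1))
        res = fit_second_level(W, GroupDesign.one_sample(5))
        assert np.isnan(res.T).all()
        np.testing.assert_allclose(res.var_E, 0.0, atol=1e-14)

    def test_two_group_contrast(self, rng):
        X = np.zeros((12, 2))
        X[:6, 0] = 1.0
        X[6:, 1] = 1.0
        W = rng.normal(size=(12, 5))
        W[:6] += 2.0
        design = GroupDesign(X_G=X, contrast_G=[1.0, -1.0])
        res = fit_second_level(W, design)
        assert res.dof == 10
        assert np.all(res.T > 0)

    def test_underdetermined_design_rejected(self):
        with pytest.raises(ValueError, match="more subjects"):
            GroupDesign(X_G=np.ones((2, 2)), contrast_G=[1.0, 0.0])


class TestBonferroni:
    def test_single_test_reduces_to_t_quantile(self):
        assert bonferroni_threshold(0.05, 1, 20) == pytest.approx(
            t_dist.isf(0.05, 20), abs=1e-12
        )

    def test_monotone_in_test_count(self):
        assert bonferroni_threshold(0.05, 52, 20) > bonferroni_threshold(0.05, 10, 20)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 52, 20)


class TestEcDensity:
    def test_height_density_at_zero_is_half(self):
        assert ec_density(0.0, 20, 0) == pytest.approx(0.5)

    def test_height_density_matches_t_tail(self):
        assert ec_density(3.96, 20, 0) == pytest.approx(
            float(t_dist.sf(3.96, 20)), abs=1e-10
        )

    def test_2d_density_decreasing_in_tail(self):
        assert ec_density(4.0, 20, 2) < ec_density(3.0, 20, 2)

    def test_unsupported_dimension(self):
        with pytest.raises(ValueError, match="d"):
            ec_density(3.0, 20, 3)


def _smooth_noise_images(rng, n_images, n, fwhm_px):
    sigma = fwhm_px / (2 * np.sqrt(2 * np.log(2)))
    out = []
    for _ in range(n_images):
        z = rng.standard_normal((n, n))
        out.append(gaussian_filter(z, sigma, mode="wrap"))
    return np.array(out)


class TestSmoothness:
    def test_known_fwhm_recovered(self, rng):
        grid = ScalpGrid2D(n=64, extent=130.0)  # pixel 4.06 mm
        fwhm_mm = 14.0
        fwhm_px = fwhm_mm / grid.pixel_size
        imgs = _smooth_noise_images(rng, 60, 64, fwhm_px)
        mask = np.ones((64, 64), bool)
        R = imgs.reshape(60, -1)
        info = estimate_smoothness(R, mask, grid)
        assert info.fwhm_mean == pytest.approx(fwhm_mm, rel=0.15)

    def test_resels_scale_with_mask_area(self, rng):
        grid = ScalpGrid2D(n=64, extent=130.0, mask=np.ones((64, 64), bool))
        imgs = _smooth_noise_images(rng, 40, 64, 4.0).reshape(40, -1)
        m1 = np.zeros((64, 64), bool)
        m1[8:24, 8:40] = True
        m2 = np.zeros((64, 64), bool)
        m2[8:40, 8:40] = True  # twice the area
        r1 = estimate_smoothness(imgs[:, m1.ravel()], m1, grid)
        r2 = estimate_smoothness(imgs[:, m2.ravel()], m2, grid)
        assert r2.resel_counts[2] / r1.resel_counts[2] == pytest.approx(2.0, rel=0.05)

    def test_simply_connected_mask_has_euler_one(self, rng):
        grid = ScalpGrid2D(n=32, extent=100.0)
        mask = np.zeros((32, 32), bool)
        mask[5:25, 5:25] = True
        R = rng.normal(size=(10, int(mask.sum())))
        info = estimate_smoothness(R, mask, grid)
        assert info.resel_counts[0] == 1.0

    def test_constant_residuals_flag_infinite_fwhm(self):
        grid = ScalpGrid2D(n=16, extent=50.0, mask=np.ones((16, 16), bool))
        R = np.ones((5, 256))
        info = estimate_smoothness(R, np.ones((16, 16), bool), grid)
        assert np.isinf(info.fwhm_est[0])
        assert info.resel_counts[2] == 0.0

    def test_mesh_smoothness_positive_and_resels_finite(self, rng, coarse_mesh):
        mask = np.ones(coarse_mesh.n_vertices, bool)
        R = rng.normal(size=(20, coarse_mesh.n_vertices))
        info = estimate_smoothness(R, mask, coarse_mesh)
        assert info.fwhm_est[0] > 0
        assert info.resel_counts[2] > 0
        # closed surface: no boundary, Euler characteristic 2
        assert info.resel_counts[0] == 2.0
        assert info.resel_counts[1] == 0.0


class TestThresholds:
    def test_point_search_region_reduces_to_t_quantile(self):
        resels = ReselInfo((10.0, 10.0), (1.0, 0.0, 0.0), 1, 1.0)
        tc = rft_peak_threshold(0.05, resels, 20)
        assert tc == pytest.approx(t_dist.isf(0.05, 20), abs=1e-5)

    def test_matches_independent_bisection(self):
        resels = ReselInfo((10.0, 10.0), (1.0, 2.0, 2.5), 100, 1.0)
        tc = rft_peak_threshold(0.05, resels, 20)
        lo, hi = 1.0, 50.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if _ec_sum(mid, resels, 20) > 0.05:
                lo = mid
            else:
                hi = mid
        assert tc == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_threshold_monotone_in_alpha(self):
        resels = ReselInfo((10.0, 10.0), (1.0, 2.0, 2.5), 100, 1.0)
        assert rft_peak_threshold(0.01, resels, 20) > rft_peak_threshold(0.05, resels, 20)

    def test_unreachable_alpha_diagnostic(self):
        resels = ReselInfo((1.0, 1.0), (1.0, 100.0, 10000.0), 100, 1.0)
        with pytest.raises(ValueError, match="unreachable"):
            rft_peak_threshold(0.05, resels, 3)

    def test_peak_p_inverse_of_threshold(self):
        resels = ReselInfo((10.0, 10.0), (1.0, 2.0, 2.5), 100, 1.0)
        tc = rft_peak_threshold(0.05, resels, 20)
        assert peak_pvalue(tc, resels, 20) == pytest.approx(0.05, abs=1e-6)

    def test_peak_p_vanishes_at_infinity(self):
        resels = ReselInfo((10.0, 10.0), (1.0, 2.0, 2.5), 100, 1.0)
        assert peak_pvalue(50.0, resels, 20) < 1e-10
        assert peak_pvalue(0.0, resels, 20) == 1.0  # capped

    def test_peak_p_matches_ec_sum(self):
        resels = ReselInfo((10.0, 10.0), (1.0, 2.0, 2.5), 100, 1.0)
        assert peak_pvalue(4.0, resels, 20) == pytest.approx(
            _ec_sum(4.0, resels, 20), abs=1e-14
        )


class TestClusters:
    def _resels(self):
        return ReselInfo((10.0, 10.0), (1.0, 2.0, 4.0), 1024, 16.0)

    def test_subthreshold_map_has_no_clusters(self):
        grid = ScalpGrid2D(n=32, extent=100.0, mask=np.ones((32, 32), bool))
        T = np.zeros((32, 32))
        out = cluster_inference(T, 3.0, self._resels(), 20, grid)
        assert out == []

    def test_two_blobs_found_with_exact_extents(self):
        grid = ScalpGrid2D(n=32, extent=100.0, mask=np.ones((32, 32), bool))
        T = np.zeros((32, 32))
        T[4:7, 4:7] = 5.0
        T[20:24, 20:22] = 6.0
        out = cluster_inference(T, 3.0, self._resels(), 20, grid)
        labels, n = label(T >= 3.0, structure=np.ones((3, 3), int))
        assert len(out) == n == 2
        assert sorted(c["k_E"] for c in out) == [8, 9]
        assert out[0]["peak_T"] == 6.0

    def test_cluster_p_decreasing_in_extent(self):
        grid = ScalpGrid2D(n=32, extent=100.0, mask=np.ones((32, 32), bool))
        ps = []
        for size in (2, 4, 8):
            T = np.zeros((32, 32))
            T[10 : 10 + size, 10:11] = 5.0
            out = cluster_inference(T, 3.0, self._resels(), 20, grid)
            ps.append(out[0]["p_FWE"])
        assert ps[0] > ps[1] > ps[2]

    def test_mesh_components_via_edges(self, coarse_mesh):
        T = np.zeros(coarse_mesh.n_vertices)
        T[coarse_mesh.vertices[:, 2] > 0.95] = 5.0
        T[coarse_mesh.vertices[:, 2] < -0.95] = 5.0
        resels = ReselInfo((20.0, 20.0), (2.0, 0.0, 5.0), coarse_mesh.n_vertices, 10.0)
        out = cluster_inference(T, 3.0, resels, 20, coarse_mesh)
        assert len(out) == 2  # two antipodal caps


class TestRunGroupInference:
    def test_bonferroni_route_delegates_threshold(self, rng):
        W = rng.normal(size=(21, 52))
        res = run_group_inference(
            None, GroupDesign.one_sample(21), alpha=0.02,
            method="bonferroni", channel_values=W,
        )
        assert res.T_c == pytest.approx(bonferroni_threshold(0.02, 52, 20), abs=1e-12)
        assert res.dof == 20

    def test_rft_route_reports_resels_and_table(self, rng):
        grid = ScalpGrid2D(n=24, extent=80.0, mask=np.ones((24, 24), bool))
        sigma = 3.0
        imgs = []
        for _ in range(12):
            z = gaussian_filter(rng.standard_normal((24, 24)), sigma, mode="wrap")
            imgs.append(_grid_image(z, grid, mask=np.ones((24, 24), bool)))
        res = run_group_inference(imgs, GroupDesign.one_sample(12), alpha=0.05)
        assert res.resels is not None and res.resels.resels > 0
        table = res.to_table()
        assert list(table.columns) == [
            "method", "space", "RESELS", "T_c", "cluster_p_FWE", "k_E", "peak_p_FWE", "T",
        ]
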