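"""Group inference: t-maps, voxelwise GLM, smoothness estimation,
Monte-Carlo cluster-extent thresholds and cluster extraction."""

import numpy as np
import pytest
from scipy import ndimage, stats

from wgbc import ScalarMap, fit_voxelwise_glm, one_sample_tmap
from wgbc.inference import (
    DesignMatrix,
    StatMap,
    connectivity_structure,
    estimate_smoothness,
    extract_clusters,
    make_design_matrix,
    monte_carlo_cluster_threshold,
)
from wgbc.preprocess import FWHM_TO_SIGMA


def _maps(arrs, affine=None):
    affine = np.eye(4) if affine is None else affine
    return [ScalarMap(a, affine) for a in arrs]


class TestOneSample:
    def test_constant_maps_with_jitter_give_large_t(self, rng):
        maps = _maps([np.ones((4, 4, 2)) + 1e-3 * rng.standard_normal((4, 4, 2)) for _ in range(6)])
        stat = one_sample_tmap(maps, np.ones((4, 4, 2), bool))
        assert (stat.t.data > 100).all()
        assert stat.df == 5

    def test_hand_computed_five_map_value(self):
        vals = [0.5, 0.7, 0.9, 1.1, 1.3]  # mean 0.9, sd sqrt(0.1)
        maps = _maps([np.full((2, 1, 1), v) for v in vals])
        maps = _maps([np.array([[[v]], [[v + 1.0]]]) for v in vals])
        stat = one_sample_tmap(maps, np.ones((2, 1, 1), bool))
        assert stat.t.data[0, 0, 0] == pytest.approx(0.9 / (np.sqrt(0.1) / np.sqrt(5)), abs=1e-10)

    def test_antisymmetric_set_gives_zero_t(self, rng):
        a = rng.standard_normal((3, 3, 1))
        maps = _maps([a, -a, 2 * a, -2 * a])
        stat = one_sample_tmap(maps, np.ones((3, 3, 1), bool))
        np.testing.assert_allclose(stat.t.data, 0.0, atol=1e-10)

    def test_needs_three_maps(self):
        with pytest.raises(ValueError):
            one_sample_tmap(_maps([np.ones((2, 2, 1))] * 2), np.ones((2, 2, 1), bool))


class TestVoxelwiseGlm:
    def test_group_only_design_equals_pooled_two_sample_t(self, rng):
        n = 14
        grp = np.repeat([0, 1], n // 2)
        maps = _maps([rng.standard_normal((5, 4, 3)) for _ in range(n)])
        design = DesignMatrix(
            np.column_stack([np.ones(n), grp]), ["intercept", "group"], [0, 1]
        )
        stat = fit_voxelwise_glm(maps, design, np.ones((5, 4, 3), bool))
        Y = np.stack([m.data.ravel() for m in maps])
        ref = stats.ttest_ind(Y[grp == 1], Y[grp == 0], equal_var=True).statistic
        np.testing.assert_allclose(stat.t.data.ravel(), ref, atol=1e-10)
        assert stat.df == n - 2

    def test_null_t_distribution_matches_student(self, rng):
        """With pure noise the contrast t follows Student t(df) across voxels."""
        n, n_vox = 20, 2000
        grp = rng.permutation(np.repeat([0, 1], n // 2))
        maps = _maps([rng.standard_normal((n_vox, 1, 1)) for _ in range(n)])
        X = np.column_stack([np.ones(n), grp, rng.standard_normal(n)])
        design = DesignMatrix(X, ["intercept", "group", "age"], [0, 1, 0])
        stat = fit_voxelwise_glm(maps, design, np.ones((n_vox, 1, 1), bool))
        t_vals = stat.t.data.ravel()
        p = stats.kstest(t_vals, stats.t(df=stat.df).cdf).pvalue
        assert p > 0.01

    def test_collinear_covariate_raises_naming_columns(self, rng):
        n = 10
        grp = np.repeat([0, 1], 5)
        maps = _maps([rng.standard_normal((2, 2, 1)) for _ in range(n)])
        X = np.column_stack([np.ones(n), grp, grp])
        design = DesignMatrix(X, ["intercept", "group", "dx"], [0, 1, 0])
        with pytest.raises(ValueError, match="group"):
            fit_voxelwise_glm(maps, design, np.ones((2, 2, 1), bool))

    def test_design_from_subject_table(self, tiny_cohort):
        design = make_design_matrix(tiny_cohort.subjects)
        assert design.columns == ["intercept", "group", "age", "sex", "education"]
        assert design.X.shape == (4, 5)
        np.testing.assert_array_equal(design.contrast, [0, 1, 0, 0, 0])


class TestEstimateSmoothness:
    def test_white_noise_reports_voxel_size(self, rng):
        mask = np.ones((20, 20, 20), bool)
        resid = rng.standard_normal((5, mask.sum()))
        fwhm = estimate_smoothness(resid, mask, np.full(3, 3.0))
        np.testing.assert_allclose(fwhm, 3.0, rtol=0.05)

    def test_recovers_applied_kernel_within_fifteen_percent(self, rng):
        mask = np.ones((24, 24, 24), bool)
        resid = []
        for _ in range(5):
            f = ndimage.gaussian_filter(
                rng.standard_normal((24, 24, 24)), 6.0 * FWHM_TO_SIGMA / 3.0, mode="wrap"
            )
            resid.append(f[mask])
        fwhm = estimate_smoothness(np.array(resid), mask, np.full(3, 3.0))
        np.testing.assert_allclose(fwhm, 6.0, rtol=0.15)

    def test_constant_residuals_fall_back(self):
        mask = np.ones((6, 6, 6), bool)
        resid = np.ones((3, mask.sum()))
        fwhm = estimate_smoothness(resid, mask, np.full(3, 3.0), fallback_fwhm_mm=6.0)
        np.testing.assert_array_equal(fwhm, [6.0, 6.0, 6.0])
        with pytest.raises(ValueError):
            estimate_smoothness(resid, mask, np.full(3, 3.0))

    def test_degenerate_mask_falls_back(self, rng):
        mask = np.zeros((6, 6, 6), bool)
        mask[:3, :3, :3] = True  # 27 voxels < 100
        resid = rng.standard_normal((3, mask.sum()))
        fwhm = estimate_smoothness(resid, mask, np.full(3, 3.0), fallback_fwhm_mm=5.0)
        np.testing.assert_array_equal(fwhm, [5.0, 5.0, 5.0])


class TestMonteCarloThreshold:
    def test_alpha_one_limit_gives_minimum_extent(self):
        mask = np.ones((10, 10, 10), bool)
        mc = monte_carlo_cluster_threshold(
            mask, 0.0, 3.0, cluster_alpha=1.0, n_iter=100, rng=0
        )
        assert mc.extent_threshold == 1

    def test_unsmoothed_suprathreshold_count_matches_binomial(self):
        """At voxel p = 0.001, one-sided, a 20^3 unsmoothed field has 8
        expected suprathreshold voxels per iteration."""
        mask = np.ones((20, 20, 20), bool)
        mc = monte_carlo_cluster_threshold(
            mask, 0.0, 3.0, voxel_p=0.001, n_iter=1000, rng=1, tails=1
        )
        counts = mc.null_supra_counts
        expect = 8000 * 0.001
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expect) < 3 * se + 1e-9

    def test_threshold_monotone_in_alpha_and_voxel_p(self):
        mask = np.ones((16, 16, 16), bool)
        kw = dict(fwhm_mm=6.0, voxel_sizes_mm=3.0, n_iter=300)
        t_loose = monte_carlo_cluster_threshold(mask, cluster_alpha=0.10, rng=5, **kw)
        t_tight = monte_carlo_cluster_threshold(mask, cluster_alpha=0.01, rng=5, **kw)
        assert t_tight.extent_threshold >= t_loose.extent_threshold
        p_loose = monte_carlo_cluster_threshold(mask, voxel_p=0.01, rng=5, **kw)
        p_tight = monte_carlo_cluster_threshold(mask, voxel_p=0.001, rng=5, **kw)
        assert p_loose.extent_threshold >= p_tight.extent_threshold

    def test_deterministic_given_seed(self):
        mask = np.ones((12, 12, 12), bool)
        a = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=200, rng=9)
        b = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=200, rng=9)
        np.testing.assert_array_equal(a.null_max_extents, b.null_max_extents)


class TestExtractClusters:
    def _stat_with_block(self, blocks, df=20, shape=(10, 10, 10)):
        t = np.zeros(shape)
        for sl, v in blocks:
            t[sl] = v
        return StatMap(t=ScalarMap(t, np.diag([3.0, 3, 3, 1])), df=df)

    def test_single_block_extent_and_peak(self):
        stat = self._stat_with_block([((slice(2, 5), slice(2, 5), slice(2, 5)), 10.0)])
        stat.t.data[3, 3, 3] = 12.0
        table = extract_clusters(stat, 0.001, extent_threshold=10)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["extent_vox"] == 27 and row["corrected"]
        assert (row["peak_i"], row["peak_j"], row["peak_k"]) == (3, 3, 3)
        assert row["peak_t"] == 12.0
        world = stat.t.affine @ np.array([3, 3, 3, 1.0])
        assert (row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"]) == tuple(world[:3])

    def test_extent_threshold_boundary_empties_table(self):
        stat = self._stat_with_block([((slice(2, 5), slice(2, 5), slice(2, 5)), 10.0)])
        table = extract_clusters(stat, 0.001, extent_threshold=28)
        assert not table["corrected"].any()

    def test_corner_touching_blocks_follow_connectivity(self):
        blocks = [
            ((slice(0, 2), slice(0, 2), slice(0, 2)), 10.0),
            ((slice(2, 4), slice(2, 4), slice(2, 4)), 10.0),
        ]
        stat = self._stat_with_block(blocks)
        six = extract_clusters(stat, 0.001, 1, connectivity=6)
        full = extract_clusters(stat, 0.001, 1, connectivity=26)
        assert len(six) == 2 and len(full) == 1

    def test_positive_and_negative_clusters_reported_separately(self):
        stat = self._stat_with_block(
            [((slice(0, 2), slice(0, 2), slice(0, 1)), 8.0),
             ((slice(7, 9), slice(7, 9), slice(8, 10)), -8.0)]
        )
        table = extract_clusters(stat, 0.001, 1)
        assert set(table["sign"]) == {1, -1}
        neg = table[table["sign"] == -1].iloc[0]
        assert neg["peak_t"] < 0

    def test_connectivity_structures(self):
        assert connectivity_structure(6).sum() == 7
        assert connectivity_structure(18).sum() == 19
        assert connectivity_structure(26).sum() == 27
        with pytest.raises(ValueError):
            connectivity_structure(10)
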