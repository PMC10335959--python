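"""Cross-voxel statistics, surrogate nulls, variograms, geometry."""
import numpy as np
import pytest

import gradmap as gm
from gradmap.spatial_stats import SeedMap


def _line_map(values, spacing=3.0):
    n = len(values)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return SeedMap(np.asarray(values, float), coords)


class TestCrossvoxelCorrelation:
    def test_trivial_and_oracle(self):
        a = _line_map([0.3, 1.2, -0.5, 2.0, 0.9])
        assert gm.crossvoxel_correlation(a, a) == pytest.approx(1.0)
        assert gm.crossvoxel_correlation(a, a.with_values(-a.values)) == pytest.approx(-1.0)
        b = a.with_values(np.array([1.0, 0.0, 2.0, -1.0, 0.5]))
        x, y = a.values, b.values
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert gm.crossvoxel_correlation(a, b) == pytest.approx(expected, abs=1e-14)

    def test_errors(self):
        a = _line_map([1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="different voxel"):
            gm.crossvoxel_correlation(a, _line_map([1, 2, 3, 4]))
        with pytest.raises(ValueError, match="zero-variance"):
            gm.crossvoxel_correlation(a, a.with_values(np.ones(5)))
        with pytest.raises(ValueError, match="3 voxels"):
            gm.crossvoxel_correlation(_line_map([1, 2]), _line_map([2, 1]))


class TestVariogram:
    def test_constant_map_warns_and_is_zero(self, cube_map):
        with pytest.warns(UserWarning, match="constant"):
            v = gm.empirical_variogram(cube_map.with_values(np.full(cube_map.n_voxels, 2.0)))
        assert np.all(v.gamma == 0)

    def test_white_noise_variogram_is_flat_at_unit_variance(self, cube_map):
        # E[0.5 (v_i - v_j)^2] = sigma^2 for iid values at any distance
        rng = np.random.default_rng(0)
        gammas = []
        for _ in range(100):
            m = cube_map.with_values(rng.standard_normal(cube_map.n_voxels))
            gammas.append(gm.empirical_variogram(m).gamma)
        mean_gamma = np.mean(gammas, axis=0)
        assert np.abs(mean_gamma - 1.0).max() < 0.1

    def test_smooth_map_variogram_increases(self, ref_results):
        v = gm.empirical_variogram(ref_results.seed_map(1))
        half = v.n_bins // 2
        assert np.all(np.diff(v.gamma[:half]) > 0)


class TestSurrogates:
    def test_multiset_preserved_exactly(self, cube_map):
        surr = gm.generate_surrogates(cube_map, n=50, seed=0)
        target = np.sort(cube_map.values)
        for s in surr.maps:
            assert np.array_equal(np.sort(s), target)

    def test_deterministic_given_seed(self, cube_map):
        a = gm.generate_surrogates(cube_map, n=20, seed=11)
        b = gm.generate_surrogates(cube_map, n=20, seed=11)
        assert np.array_equal(a.maps, b.maps)

    def test_variogram_match_on_fitted_gradient_map(self, ref_results):
        m = ref_results.seed_map(1)
        surr = gm.generate_surrogates(m, n=200, seed=3)
        fit = surr.variogram_fit
        rel = np.abs(fit["surrogate_gamma_mean"] / fit["observed_gamma"] - 1)
        assert rel[: len(rel) // 2].max() < 0.2

    def test_errors(self, cube_map):
        with pytest.raises(ValueError):
            gm.generate_surrogates(cube_map, n=0)


class TestPermutationPvalue:
    def test_smooth_self_correlation_is_significant(self, ref_results):
        g = ref_results.seed_map(1)
        surr = gm.generate_surrogates(g, n=200, seed=0)
        res = gm.permutation_pvalue(g, g, surr)
        assert res.r_observed == pytest.approx(1.0)
        assert res.p_perm <= 0.05

    def test_p_is_a_count_over_n(self, cube_map):
        rng = np.random.default_rng(5)
        y = cube_map.with_values(rng.standard_normal(cube_map.n_voxels))
        surr = gm.generate_surrogates(cube_map, n=250, seed=1)
        res = gm.permutation_pvalue(cube_map, y, surr)
        assert res.n_surrogates == 250
        assert (res.p_perm * 250) == pytest.approx(round(res.p_perm * 250))

    def test_tail_conventions(self, cube_map):
        rng = np.random.default_rng(6)
        y = cube_map.with_values(rng.standard_normal(cube_map.n_voxels))
        surr = gm.generate_surrogates(cube_map, n=99, seed=2)
        auto = gm.permutation_pvalue(cube_map, y, surr)
        fixed = gm.permutation_pvalue(cube_map, y, surr, tail=auto.tail)
        assert auto.p_perm == fixed.p_perm
        up = gm.permutation_pvalue(cube_map, y, surr, tail="greater")
        dn = gm.permutation_pvalue(cube_map, y, surr, tail="less")
        # the two fixed tails cover the null distribution (ties aside)
        assert up.p_perm + dn.p_perm <= 1.0
        with pytest.raises(ValueError):
            gm.permutation_pvalue(cube_map, y, surr, tail="two-sided")

    def test_p_floor_formatting(self):
        res = gm.PermutationResult(r_observed=0.9, p_perm=0.0, n_surrogates=5000, tail="greater")
        assert res.format_p() == "< 0.0002"


class TestDistanceMap:
    def test_collinear_arithmetic(self):
        m = _line_map([1.0, 2.0, 5.0][::-1])  # peak at index 0
        d = gm.euclidean_distance_map(m)
        assert np.array_equal(d.values, [0.0, 3.0, 6.0])

    def test_peak_distance_zero_and_tie_warning(self):
        m = _line_map([1.0, 3.0, 3.0, 0.0])
        with pytest.warns(UserWarning, match="tie"):
            d = gm.euclidean_distance_map(m)
        assert d.values[1] == 0.0  # lowest linear index wins

    def test_shift_invariance_and_translation_equivariance(self, cube_map):
        d0 = gm.euclidean_distance_map(cube_map)
        d1 = gm.euclidean_distance_map(cube_map.with_values(cube_map.values + 42.0))
        assert np.array_equal(d0.values, d1.values)
        moved = SeedMap(cube_map.values, cube_map.coords_mm + [10.0, -4.0, 2.0], cube_map.hemisphere)
        d2 = gm.euclidean_distance_map(moved)
        assert np.allclose(d0.values, d2.values)

    def test_monotone_gradient_anticorrelates_with_distance(self, ref_results):
        g = ref_results.seed_map(1)
        d = gm.euclidean_distance_map(g)
        assert gm.crossvoxel_correlation(g, d) < 0


class TestPerHemisphere:
    def test_mirror_symmetric_map_gives_identical_halves(self):
        coords = np.argwhere(np.ones((6, 3, 3), bool)) * 2.0
        vals = np.cos(coords[:, 1]) + 0.1 * coords[:, 2]  # independent of x
        hemi = np.where(coords[:, 0] < 6.0, "L", "R")
        m = SeedMap(vals, coords, hemi)

        def analyze(sub):
            return gm.crossvoxel_correlation(sub, gm.euclidean_distance_map(sub))

        res = gm.per_hemisphere(analyze, m)
        assert res["L"] == pytest.approx(res["R"], abs=1e-12)

    def test_partition_and_locality(self, cube_map):
        left = cube_map.hemisphere == "L"
        assert left.sum() + (~left).sum() == cube_map.n_voxels
        perturbed = cube_map.values.copy()
        perturbed[~left] += 5.0  # confined to the right hemisphere
        m2 = cube_map.with_values(perturbed)

        def peak_value(sub):
            return sub.values.max()

        a = gm.per_hemisphere(peak_value, cube_map)
        b = gm.per_hemisphere(peak_value, m2)
        assert a["L"] == b["L"]
        assert a["R"] != b["R"]

    def test_errors(self, cube_map):
        with pytest.raises(ValueError, match="hemisphere"):
            gm.per_hemisphere(lambda s: None, SeedMap(cube_map.values, cube_map.coords_mm))
        one_sided = SeedMap(cube_map.values, cube_map.coords_mm, np.full(cube_map.n_voxels, "L"))
        with pytest.raises(ValueError, match="empty"):
            gm.per_hemisphere(lambda s: None, one_sided)
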