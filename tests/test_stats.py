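"""Voxel-wise correlation engine and cluster/concordance filtering."""
import numpy as np
import pytest
from scipy import stats as sstats

from imiomics.errors import ValidationError
from imiomics.grids import ImageGrid3D, ScalarVolume
from imiomics.stats import (
    VolumeStack,
    concordance_filter,
    p_value_map,
    pearson_map,
    spearman_map,
    threshold_clusters,
)


def _stack(data):
    data = np.asarray(data, dtype=float)
    grid = ImageGrid3D(data.shape[1:], (1.0, 1.0, 1.0))
    return VolumeStack(grid, data, [f"s{i}" for i in range(data.shape[0])])


def _single_voxel_stack(series):
    data = np.asarray(series, dtype=float).reshape(-1, 1, 1, 1)
    return _stack(data)


class TestPearson:
    def test_perfect_correlation_when_series_equals_covariate(self, rng):
        x = rng.normal(size=6)
        data = np.tile(x.reshape(-1, 1, 1, 1), (1, 3, 3, 3))
        r = pearson_map(_stack(data), x)
        assert np.allclose(r.r, 1.0)

    def test_hand_computed_example(self):
        r = pearson_map(_single_voxel_stack([1, 3, 2, 4]), [1, 2, 3, 4])
        assert r.r[0, 0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_constant_voxel_is_undefined_not_nan_poisoned(self, rng):
        data = rng.normal(size=(5, 2, 2, 2))
        data[:, 0, 0, 0] = 3.0
        r = pearson_map(_stack(data), rng.normal(size=5))
        assert np.isnan(r.r[0, 0, 0])
        assert np.isfinite(r.r[1:, :, :]).all()

    def test_length_mismatch_and_constant_covariate_rejected(self, rng):
        st = _stack(rng.normal(size=(5, 2, 2, 2)))
        with pytest.raises(ValidationError):
            pearson_map(st, np.ones(4))
        with pytest.raises(ValidationError):
            pearson_map(st, np.ones(5))

    def test_agrees_with_scipy_loop_oracle(self, rng):
        data = rng.normal(size=(9, 5, 4, 3))
        x = rng.normal(size=9)
        r = pearson_map(_stack(data), x)
        for idx in np.ndindex(data.shape[1:]):
            expected = sstats.pearsonr(data[(slice(None),) + idx], x).statistic
            assert r.r[idx] == pytest.approx(expected, abs=1e-12)


class TestPValues:
    def test_zero_correlation_gives_p_one(self):
        r = pearson_map(_single_voxel_stack([1, -1, -1, 1]), [1, 2, 3, 4])
        assert p_value_map(r).values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_correlation_gives_p_zero(self):
        r = pearson_map(_single_voxel_stack([1, 2, 3, 4]), [1, 2, 3, 4])
        assert p_value_map(r).values[0, 0, 0] == 0.0

    def test_undefined_voxels_get_p_one(self, rng):
        data = rng.normal(size=(5, 2, 2, 2))
        data[:, 1, 1, 1] = 0.0
        p = p_value_map(pearson_map(_stack(data), rng.normal(size=5)))
        assert p.values[1, 1, 1] == 1.0

    def test_matches_scipy_t_distribution_p(self, rng):
        data = rng.normal(size=(8, 3, 3, 3))
        x = rng.normal(size=8)
        r = pearson_map(_stack(data), x)
        p = p_value_map(r)
        for idx in np.ndindex(data.shape[1:]):
            expected = sstats.pearsonr(data[(slice(None),) + idx], x).pvalue
            assert p.values[idx] == pytest.approx(expected, abs=1e-6)


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(size=7)
        data = np.tile(np.exp(x).reshape(-1, 1, 1, 1), (1, 2, 2, 2))
        rho = spearman_map(_stack(data), x)
        assert np.allclose(rho.r, 1.0)

    def test_hand_computed_example(self):
        rho = spearman_map(_single_voxel_stack([1, 3, 2, 4]), [1, 2, 3, 4])
        assert rho.r[0, 0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_ties_use_midranks(self):
        rho = spearman_map(_single_voxel_stack([1, 1, 2, 2]), [1, 2, 3, 4])
        expected = sstats.spearmanr([1, 1, 2, 2], [1, 2, 3, 4]).statistic
        assert rho.r[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_increasing_covariate_transform(self, rng):
        data = rng.normal(size=(8, 3, 3, 3))
        x = rng.normal(size=8)
        a = spearman_map(_stack(data), x)
        b = spearman_map(_stack(data), np.exp(2 * x) + 5)
        assert np.allclose(a.r, b.r, atol=1e-12)


def _maps_from_r(r_values, n=20):
    grid = ImageGrid3D(r_values.shape, (1.0, 1.0, 1.0))
    from imiomics.stats import CorrelationMap

    rmap = CorrelationMap(grid, r_values, n, "pearson", "x")
    return rmap, p_value_map(rmap)


class TestThresholdClusters:
    def test_single_voxel_below_min_size_is_dropped(self):
        r = np.zeros((8, 8, 8))
        r[4, 4, 4] = 0.9
        cs = threshold_clusters(*_maps_from_r(r), min_size=5)
        assert len(cs) == 0

    def test_supra_threshold_block_forms_one_positive_cluster(self):
        r = np.zeros((9, 9, 9))
        r[3:6, 3:6, 3:6] = 0.6
        cs = threshold_clusters(*_maps_from_r(r), min_size=5)
        assert len(cs) == 1
        c = cs.clusters[0]
        assert c.size == 27 and c.sign == 1 and c.all_p_below

    def test_component_with_one_non_significant_voxel_is_rejected(self):
        # two separated blocks; one contains a weak-|r| (high-p) member voxel
        from imiomics.stats import CorrelationMap

        r = np.zeros((12, 8, 8))
        r[1:4, 2:5, 2:5] = 0.8
        r[8:11, 2:5, 2:5] = 0.8
        r[9, 3, 3] = 0.55  # still supra-threshold but p > 0.05 at n=12
        grid = ImageGrid3D(r.shape, (1.0, 1.0, 1.0))
        rmap = CorrelationMap(grid, r, 12, "pearson", "x")
        cs = threshold_clusters(rmap, p_value_map(rmap), min_size=5)
        assert len(cs) == 1
        assert cs.clusters[0].voxels[:, 0].max() < 8

    def test_components_match_brute_force_flood_fill(self, rng):
        r = np.where(rng.uniform(size=(10, 10, 10)) > 0.7, 0.9, 0.0)
        cs = threshold_clusters(*_maps_from_r(r), min_size=1)
        # brute-force 26-connected flood fill
        supra = r > 0.5
        seen = np.zeros_like(supra)
        comps = []
        for start in np.argwhere(supra):
            if seen[tuple(start)]:
                continue
            stack, comp = [tuple(start)], set()
            seen[tuple(start)] = True
            while stack:
                v = stack.pop()
                comp.add(v)
                for d in np.ndindex(3, 3, 3):
                    nb = tuple(np.array(v) + np.array(d) - 1)
                    if all(0 <= nb[i] < 10 for i in range(3)) and supra[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            comps.append(frozenset(comp))
        found = {frozenset(map(tuple, c.voxels)) for c in cs.clusters}
        assert found == set(comps)

    def test_union_of_clusters_is_within_supra_threshold_set(self, rng):
        r = np.clip(rng.normal(scale=0.4, size=(10, 10, 10)), -0.99, 0.99)
        rmap, pmap = _maps_from_r(r, n=30)
        cs = threshold_clusters(rmap, pmap, min_size=1)
        assert not (cs.total_mask() & ~(np.abs(r) > 0.5)).any()


class TestConcordance:
    def _clusters(self, r, n=40):
        rmap, pmap = _maps_from_r(r, n=n)
        return threshold_clusters(rmap, pmap, min_size=5), rmap

    def test_identical_sexes_with_rho_equal_r_retain_everything(self):
        r = np.zeros((9, 9, 9))
        r[2:6, 2:6, 2:6] = 0.7
        cs_f, rmap = self._clusters(r)
        cs_m, _ = self._clusters(r)
        kept_f, kept_m = concordance_filter(cs_f, cs_m, rmap, rmap)
        assert len(kept_f) == len(cs_f) == 1
        assert len(kept_m) == 1
        assert kept_f.clusters[0].sex_concordant and kept_f.clusters[0].spearman_concordant

    def test_cluster_present_in_one_sex_only_is_removed(self):
        r_f = np.zeros((9, 9, 9))
        r_f[2:6, 2:6, 2:6] = 0.7
        cs_f, rmap_f = self._clusters(r_f)
        cs_m, rmap_m = self._clusters(np.zeros((9, 9, 9)))
        kept_f, kept_m = concordance_filter(cs_f, cs_m, rmap_f, rmap_m)
        assert len(kept_f) == 0 and len(kept_m) == 0

    def test_sign_mismatch_blocks_retention(self):
        r_f = np.zeros((9, 9, 9))
        r_f[2:6, 2:6, 2:6] = 0.7
        cs_f, rmap_f = self._clusters(r_f)
        cs_m, rmap_m = self._clusters(-r_f)
        kept_f, _ = concordance_filter(cs_f, cs_m, rmap_f, rmap_m)
        assert len(kept_f) == 0
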