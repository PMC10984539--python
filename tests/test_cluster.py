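"""Sign-flip permutation cluster statistics over space × time."""

import numpy as np
import pytest

from memfusion.cluster import (
    ClusterConfig,
    baseline_cluster_threshold,
    find_clusters,
    permutation_cluster_test,
)
from memfusion.rdm import time_axis_ms


def flood_fill(binary_map, neighbors_fn):
    """Brute-force connected components by stack-based flood fill."""
    visited = np.zeros(binary_map.shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(binary_map)):
        if visited[start]:
            continue
        stack, members = [start], []
        visited[start] = True
        while stack:
            cur = stack.pop()
            members.append(cur)
            for nxt in neighbors_fn(cur):
                if all(0 <= c < s for c, s in zip(nxt, binary_map.shape)) and binary_map[nxt] and not visited[nxt]:
                    visited[nxt] = True
                    stack.append(nxt)
        components.append(frozenset(members))
    return components


def neighbors_26_time(coord):
    """26-neighborhood in space at the same sample, ±1 sample at the same voxel."""
    x, y, z, t = coord
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0):
                    out.append((x + dx, y + dy, z + dz, t))
    out += [(x, y, z, t - 1), (x, y, z, t + 1)]
    return out


class TestBaselineThreshold:
    def setup_method(self):
        self.t = time_axis_ms(-200, 400, 10)

    def wrap(self, baseline_values):
        """Place given values in the baseline period of a 1-voxel map."""
        n_base = int((self.t < 0).sum())
        assert len(baseline_values) == n_base
        vol = np.zeros((1, 1, 1, self.t.size))
        vol[0, 0, 0, : n_base] = baseline_values
        vol[0, 0, 0, n_base:] = np.median(baseline_values)
        return vol

    def test_constant_baseline_returns_that_constant(self):
        cfg = ClusterConfig()
        assert baseline_cluster_threshold(self.wrap([3.5] * 20), self.t, cfg) == 3.5

    def test_quantile_matches_sorting_oracle(self, rng):
        values = rng.permutation(np.arange(1, 1001, dtype=float))
        vol = np.zeros((50, 1, 1, self.t.size))
        vol[..., self.t < 0] = values.reshape(50, 1, 1, 20)
        for p in (0.001, 0.01, 0.05, 0.25):
            cfg = ClusterConfig(cluster_def_p=p)
            got = baseline_cluster_threshold(vol, self.t, cfg)
            srt = np.sort(values)
            expected = srt[max(int(np.ceil((1 - p) * 1000)), 1) - 1]
            assert got == expected

    def test_p_equal_one_returns_minimum(self, rng):
        values = rng.random(20) + 5
        cfg = ClusterConfig(cluster_def_p=1.0)
        assert baseline_cluster_threshold(self.wrap(values), self.t, cfg) == values.min()

    def test_empty_mask_rejected(self, rng):
        cfg = ClusterConfig()
        with pytest.raises(ValueError, match="mask"):
            baseline_cluster_threshold(self.wrap(rng.random(20)), self.t, cfg, mask=np.zeros((1, 1, 1), dtype=bool))


class TestFindClusters:
    def test_empty_map_has_no_clusters(self):
        assert find_clusters(np.zeros((3, 3, 3, 5), dtype=bool)) == []

    def test_isolated_voxel_timepoint_is_singleton(self):
        m = np.zeros((4, 4, 4, 6), dtype=bool)
        m[2, 1, 3, 4] = True
        clusters = find_clusters(m)
        assert len(clusters) == 1 and clusters[0][0] == 1

    def test_two_separated_blobs(self):
        m = np.zeros((8, 8, 8, 10), dtype=bool)
        m[0:2, 0:2, 0:2, 0:2] = True  # 16 voxel-timepoints
        m[5:8, 5:8, 5:8, 6:9] = True  # 81 voxel-timepoints
        clusters = find_clusters(m)
        assert [c[0] for c in clusters] == [81, 16]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((5, 5, 5, 8)) < 0.2
        got = {frozenset(map(tuple, coords)) for _, coords in find_clusters(m)}
        expected = set(flood_fill(m, neighbors_26_time))
        assert got == expected


class TestPermutationTest:
    def setup_method(self):
        self.t = time_axis_ms(-200, 400, 10)
        self.cfg = ClusterConfig(n_permutations=200, alpha=0.01, seed=0)

    def test_all_zero_maps_give_no_clusters(self):
        maps = np.zeros((4, 3, 3, 3, self.t.size))
        res = permutation_cluster_test(maps, self.t, self.cfg)
        assert res.clusters == []
        assert not res.significant_mask.any()

    def test_planted_blob_is_significant_at_floor_p(self, rng):
        maps = rng.standard_normal((15, 6, 6, 6, self.t.size))
        maps[:, 2:5, 2:5, 2:5, 30:50] += 1.5
        res = permutation_cluster_test(maps, self.t, self.cfg)
        top = res.clusters[0]
        assert top.p_value == pytest.approx(1 / 201)
        assert top.p_value < self.cfg.alpha
        # the significant mask covers the planted blob
        blob = np.zeros_like(res.significant_mask)
        blob[2:5, 2:5, 2:5, 30:50] = True
        assert (res.significant_mask & blob).sum() >= 0.9 * blob.sum()

    def test_enlarging_a_blob_never_raises_its_p(self, rng):
        base = rng.standard_normal((15, 6, 6, 6, self.t.size))
        small = base.copy()
        small[:, 2:4, 2:4, 2:4, 30:40] += 1.5
        large = base.copy()
        large[:, 2:5, 2:5, 2:5, 28:50] += 1.5
        p_small = permutation_cluster_test(small, self.t, self.cfg).clusters[0].p_value
        p_large = permutation_cluster_test(large, self.t, self.cfg).clusters[0].p_value
        assert p_large <= p_small

    def test_seeded_result_reproduces_bit_exactly(self, rng):
        maps = rng.standard_normal((6, 4, 4, 4, self.t.size))
        a = permutation_cluster_test(maps, self.t, self.cfg)
        b = permutation_cluster_test(maps, self.t, self.cfg)
        assert np.array_equal(a.null_max_sizes, b.null_max_sizes)
        assert a.threshold_value == b.threshold_value
        assert [c.size for c in a.clusters] == [c.size for c in b.clusters]

    def test_subject_order_does_not_change_observed_statistics(self, rng):
        maps = rng.standard_normal((8, 4, 4, 4, self.t.size))
        a = permutation_cluster_test(maps, self.t, self.cfg)
        b = permutation_cluster_test(maps[::-1], self.t, self.cfg)
        assert a.threshold_value == pytest.approx(b.threshold_value)
        assert sorted(c.size for c in a.clusters) == sorted(c.size for c in b.clusters)
        # the null distributions agree distributionally
        assert abs(a.null_max_sizes.mean() - b.null_max_sizes.mean()) <= 3.0

    def test_insufficient_permutations_warn(self, rng):
        maps = rng.standard_normal((4, 3, 3, 3, self.t.size))
        with pytest.warns(UserWarning, match="permutations"):
            permutation_cluster_test(maps, self.t, ClusterConfig(n_permutations=50, alpha=0.01, seed=0))

    def test_nan_voxels_never_enter_clusters(self, rng):
        maps = rng.standard_normal((15, 5, 5, 5, self.t.size))
        maps[:, 0, 0, 0, :] = np.nan
        maps[:, 2:4, 2:4, 2:4, 30:50] += 2.0
        res = permutation_cluster_test(maps, self.t, self.cfg)
        for c in res.clusters:
            assert not ((c.coordinates[:, :3] == 0).all(axis=1)).any()
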