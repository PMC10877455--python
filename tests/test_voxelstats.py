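"""Stage-1 inference: residualization, Welch t, clustering, permutation FWE."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from depstrat.core import VolumeGrid
from depstrat.voxelstats import (
    ContrastSpec,
    cluster_fwe,
    enumerate_contrasts,
    form_clusters,
    nuisance_design,
    residualize,
    welch_t,
)


def _covars(n, rng):
    return pd.DataFrame(
        {
            "age": rng.uniform(45, 80, n),
            "sex": rng.integers(0, 2, n),
            "tiv_ml": rng.normal(1450, 120, n),
        }
    )


class TestDesign:
    def test_48_contrasts_per_strategy(self):
        for strategy in ("pool", "matched"):
            contrasts = enumerate_contrasts(strategy)
            assert len(contrasts) == 48
            assert len(set(contrasts)) == 48

    def test_12_possible_masks_per_measure(self):
        contrasts = enumerate_contrasts()
        for modality in ("falff", "lcor", "gcor", "gmv"):
            assert sum(c.modality == modality for c in contrasts) == 12

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ContrastSpec(0, "falff", "decrease")
        with pytest.raises(ValueError):
            ContrastSpec(1, "falff", "sideways")


class TestResidualize:
    def test_exact_linear_function_of_age_removed(self, rng):
        cov = _covars(40, rng)
        stack = np.outer(2.0 * cov["age"] + 5.0, np.ones(30))
        res = residualize(stack, cov)
        assert np.abs(res).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        cov = _covars(50, rng)
        stack = rng.standard_normal((50, 20))
        res = residualize(stack, cov)
        design = nuisance_design(cov)
        assert np.abs(design.T @ res).max() < 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        cov = _covars(30, rng)
        cov["sex"] = 1  # constant column collides with intercept
        with pytest.raises(ValueError, match="rank deficient"):
            residualize(rng.standard_normal((30, 5)), cov)

    def test_misaligned_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            residualize(rng.standard_normal((10, 5)), _covars(12, rng))


class TestWelch:
    def test_closed_form_example(self):
        # {1,2,3} vs {4,5,6}: means 2 and 5, both variances 1 ->
        # t = -3/sqrt(2/3) = -3.674, Satterthwaite df = 4
        stack = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        labels = np.array([True, True, True, False, False, False])
        t, df = welch_t(stack, labels)
        assert t[0] == pytest.approx(-3.674, abs=1e-3)
        assert df[0] == pytest.approx(4.0, abs=1e-9)

    def test_identical_groups_give_zero(self):
        vals = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        labels = np.array([True, True, True, False, False, False])
        t, _ = welch_t(vals, labels)
        assert t[0] == 0.0

    def test_equal_n_equal_var_matches_pooled_t(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        y = (y - y.mean()) / y.std(ddof=1) * x.std(ddof=1)  # equal variances
        stack = np.concatenate([x, y])[:, None]
        labels = np.zeros(40, dtype=bool)
        labels[:20] = True
        t, _ = welch_t(stack, labels)
        sp = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        pooled = (x.mean() - y.mean()) / (sp * np.sqrt(2 / 20))
        assert t[0] == pytest.approx(pooled, abs=1e-12)

    def test_sign_convention_case_minus_control(self):
        stack = np.array([[0.0], [0.1], [-0.1], [5.0], [5.1], [4.9]])
        labels = np.array([True, True, True, False, False, False])
        t, _ = welch_t(stack, labels)
        assert t[0] < 0  # cases lower -> negative

    def test_matches_scipy(self, rng):
        stack = rng.standard_normal((30, 50))
        labels = np.zeros(30, dtype=bool)
        labels[:12] = True
        t, df = welch_t(stack, labels)
        from scipy import stats as sps

        ref = sps.ttest_ind(stack[labels], stack[~labels], equal_var=False, axis=0)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(df, ref.df, atol=1e-8)

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(ValueError):
            welch_t(rng.standard_normal((4, 3)), np.array([True, False, False, False]))


def floodfill_sizes(supra):
    """BFS flood-fill oracle for 26-connected component sizes."""
    visited = np.zeros_like(supra, dtype=bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    sizes = []
    for start in map(tuple, np.argwhere(supra)):
        if visited[start]:
            continue
        q = deque([start])
        visited[start] = True
        size = 0
        while q:
            x, y, z = q.popleft()
            size += 1
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[a] < supra.shape[a] for a in range(3)):
                    if supra[n] and not visited[n]:
                        visited[n] = True
                        q.append(n)
        sizes.append(size)
    return sorted(sizes)


class TestClusters:
    def test_zero_map_gives_no_clusters(self, grid8):
        clusters, _ = form_clusters(
            np.zeros(grid8.shape), np.full(grid8.shape, 30.0), grid8
        )
        assert clusters == []

    def test_single_block_cluster(self, grid8):
        t_map = np.zeros(grid8.shape)
        t_map[2:5, 2:5, 2:5] = -10.0
        clusters, _ = form_clusters(
            t_map, np.full(grid8.shape, 30.0), grid8, direction="decrease"
        )
        assert len(clusters) == 1
        assert clusters[0].size == 27

    def test_direction_respected(self, grid8):
        t_map = np.zeros(grid8.shape)
        t_map[1, 1, 1] = 10.0
        df = np.full(grid8.shape, 30.0)
        inc, _ = form_clusters(t_map, df, grid8, direction="increase")
        dec, _ = form_clusters(t_map, df, grid8, direction="decrease")
        assert len(inc) == 1 and dec == []

    def test_sizes_match_floodfill_oracle(self, rng):
        grid = VolumeGrid.full((10, 10, 10))
        t_map = rng.standard_normal(grid.shape) * 3.0
        df = np.full(grid.shape, 40.0)
        clusters, _ = form_clusters(t_map, df, grid, p_voxel=0.05, direction="increase")
        from scipy import stats as sps

        thr = sps.t.isf(0.05, 40.0)
        assert floodfill_sizes(t_map > thr) == sorted(c.size for c in clusters)


class TestClusterFwe:
    def _planted(self, rng, n=30, effect=0.0, grid=None):
        grid = grid or VolumeGrid.full((10, 10, 10))
        stack = rng.standard_normal((2 * n, grid.n_voxels))
        labels = np.zeros(2 * n, dtype=bool)
        labels[:n] = True
        if effect:
            sphere = np.zeros(grid.shape, dtype=bool)
            sphere[3:7, 3:7, 3:7] = True
            stack[labels] += effect * grid.flatten(sphere.astype(float))
        return grid, stack, labels

    def test_pvalue_floor_when_observed_exceeds_all_perms(self, rng):
        grid, stack, labels = self._planted(rng, n=30, effect=-3.0)
        res = cluster_fwe(stack, labels, grid, n_perm=150, seed=0)
        assert len(res.cluster_table) >= 1
        assert res.cluster_table["p_corrected"].min() == pytest.approx(1 / 151)

    def test_pvalues_within_valid_range_and_reproducible(self, rng):
        grid, stack, labels = self._planted(rng, n=20)
        a = cluster_fwe(stack, labels, grid, n_perm=120, seed=5, p_voxel=0.05)
        b = cluster_fwe(stack, labels, grid, n_perm=120, seed=5, p_voxel=0.05)
        assert np.array_equal(a.perm_max_sizes, b.perm_max_sizes)
        pd.testing.assert_frame_equal(a.cluster_table, b.cluster_table)
        if len(a.cluster_table):
            p = a.cluster_table["p_corrected"]
            assert ((p >= 1 / 121) & (p <= 1.0)).all()

    def test_mask_voxels_exceed_threshold_in_direction(self, rng):
        grid, stack, labels = self._planted(rng, n=30, effect=-3.0)
        res = cluster_fwe(stack, labels, grid, n_perm=150, seed=1, direction="decrease")
        assert res.significance_mask.any()
        assert (res.t_map[res.significance_mask] < 0).all()
        assert res.significance_mask[~grid.mask].sum() == 0

    def test_planted_sphere_recovered_with_dice_above_half(self, rng):
        # recovery simulation: standardized shift of 1 inside a sphere
        grid, stack, labels = self._planted(rng, n=60, effect=-1.0)
        res = cluster_fwe(stack, labels, grid, n_perm=300, seed=2, direction="decrease")
        sphere = np.zeros(grid.shape, dtype=bool)
        sphere[3:7, 3:7, 3:7] = True
        inter = np.logical_and(res.significance_mask, sphere).sum()
        dice = 2 * inter / (res.significance_mask.sum() + sphere.sum())
        assert dice > 0.5

    def test_insufficient_permutations_rejected(self, rng):
        grid, stack, labels = self._planted(rng, n=10)
        with pytest.raises(ValueError):
            cluster_fwe(stack, labels, grid, n_perm=100, alpha_cluster=0.005)
        with pytest.raises(ValueError):
            cluster_fwe(stack, labels, grid, n_perm=50)
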