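"""Group sampling and the voxel-wise two-sample t map."""

import numpy as np
import pytest
from scipy import stats

import pipefpr as pf


class TestSampleGroups:
    def test_disjoint_and_exhaustive_on_small_pool(self, rng):
        a = pf.sample_groups([0, 1, 2, 3], 2, rng)
        assert set(a.group1_ids).isdisjoint(a.group2_ids)
        assert set(a.group1_ids) | set(a.group2_ids) == {0, 1, 2, 3}

    def test_same_seed_reproduces_assignment(self):
        r1 = np.random.default_rng(5)
        r2 = np.random.default_rng(5)
        pool = list(range(100))
        assert pf.sample_groups(pool, 10, r1) == pf.sample_groups(pool, 10, r2)

    def test_pool_too_small_raises(self, rng):
        with pytest.raises(ValueError, match="pool"):
            pf.sample_groups([1, 2, 3], 2, rng)

    def test_inclusion_frequency_uniform_over_pool(self, rng):
        """Each subject selected ≈ 100/1080 of the time over many draws."""
        pool = np.arange(1080)
        n_draws = 10_000
        counts = np.zeros(1080)
        for _ in range(n_draws):
            a = pf.sample_groups(pool, 50, rng)
            counts[list(a.group1_ids + a.group2_ids)] += 1
        p = 100 / 1080
        se = np.sqrt(p * (1 - p) / n_draws)
        dev = np.abs(counts / n_draws - p)
        # ~0.3% of subjects are expected beyond 3 SE by chance alone
        assert (dev <= 3 * se).mean() > 0.985
        assert dev.max() <= 5 * se


class TestTwoSampleTmap:
    def test_identical_groups_give_zero_t(self, rng):
        x = [rng.normal(size=(8, 8, 8)) for _ in range(4)]
        res = pf.two_sample_tmap(x, [v.copy() for v in x], np.ones((8, 8, 8), bool))
        np.testing.assert_allclose(res.t_in_mask(), 0.0, atol=1e-12)

    def test_single_voxel_pooled_t_matches_scipy(self):
        g1 = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0, 4.0)]
        g2 = [np.full((1, 1, 1), v) for v in (5.0, 6.0, 7.0, 8.0)]
        mask = np.ones((1, 1, 1), bool)
        res = pf.two_sample_tmap(g1, g2, mask, variance_mode="pooled")
        oracle = stats.ttest_ind([1, 2, 3, 4], [5, 6, 7, 8], equal_var=True)
        assert res.t_in_mask()[0] == pytest.approx(oracle.statistic)
        # hand computation: diff -4, sp^2 = 5/3, se = sqrt(sp^2 * 1/2)
        assert res.t_in_mask()[0] == pytest.approx(-4.38178, abs=1e-5)
        assert res.df == 6.0

    def test_single_voxel_welch_matches_scipy(self, rng):
        a, b = rng.normal(size=7), rng.normal(size=5) * 3.0
        res = pf.two_sample_tmap(
            [np.full((1, 1, 1), v) for v in a],
            [np.full((1, 1, 1), v) for v in b],
            np.ones((1, 1, 1), bool),
        )
        oracle = stats.ttest_ind(a, b, equal_var=False)
        assert res.t_in_mask()[0] == pytest.approx(oracle.statistic)
        assert float(np.asarray(res.df)[0, 0, 0]) == pytest.approx(oracle.df)

    def test_fifty_per_group_pooled_df_is_98(self, rng):
        g1 = [rng.normal(size=(4, 4, 4)) for _ in range(50)]
        g2 = [rng.normal(size=(4, 4, 4)) for _ in range(50)]
        res = pf.two_sample_tmap(g1, g2, np.ones((4, 4, 4), bool), "pooled")
        assert res.df == 98.0
        assert res.df_scalar == 98.0

    def test_direction_antisymmetry(self, rng):
        g1 = [rng.normal(size=(6, 6, 6)) for _ in range(5)]
        g2 = [rng.normal(size=(6, 6, 6)) for _ in range(5)]
        mask = np.ones((6, 6, 6), bool)
        fwd = pf.two_sample_tmap(g1, g2, mask, direction="group1_gt_group2")
        rev = pf.two_sample_tmap(g1, g2, mask, direction="group2_gt_group1")
        np.testing.assert_allclose(fwd.t_in_mask(), -rev.t_in_mask())

    def test_welch_equals_pooled_for_equal_group_variances(self, rng):
        g1 = [rng.normal(size=(5, 5, 5)) for _ in range(6)]
        g2 = [1.0 - v for v in g1]  # same per-voxel sample variance, equal n
        mask = np.ones((5, 5, 5), bool)
        welch = pf.two_sample_tmap(g1, g2, mask, "welch")
        pooled = pf.two_sample_tmap(g1, g2, mask, "pooled")
        np.testing.assert_allclose(welch.t_in_mask(), pooled.t_in_mask())
        np.testing.assert_allclose(np.asarray(welch.df), pooled.df)

    def test_zero_variance_voxel_flagged_and_excluded(self, rng):
        g1 = [rng.normal(size=(4, 4, 4)) for _ in range(4)]
        g2 = [rng.normal(size=(4, 4, 4)) for _ in range(4)]
        for v in g1 + g2:
            v[0, 0, 0] = 1.0  # degenerate voxel in both groups
        res = pf.two_sample_tmap(g1, g2, np.ones((4, 4, 4), bool))
        assert res.n_undefined == 1
        assert not res.valid_mask[0, 0, 0]
        assert res.t_in_mask().size == 63

    def test_residual_maps_are_standardized(self, rng):
        g1 = [rng.normal(size=(4, 4, 4)) for _ in range(10)]
        g2 = [rng.normal(size=(4, 4, 4)) for _ in range(10)]
        res = pf.two_sample_tmap(g1, g2, np.ones((4, 4, 4), bool))
        r = res.residual_maps
        assert r.shape == (20, 4, 4, 4)
        np.testing.assert_allclose(r[:10].mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(r[:10].std(axis=0, ddof=1), 1.0, atol=1e-5)


class TestNullDistribution:
    def test_null_t_matches_student_98_moments(self):
        """Same-pipeline null t values pooled over draws ≈ Student(98).

        Uses a cohort without the scalar subject effect: that effect keeps
        each voxel's t marginally Student but adds a map-wide common mode
        that would need hundreds of draws to average out of the moments.
        """
        spec = pf.PipelineSpec(label="a", unit_scale=1.0)
        config = pf.CohortConfig(
            pipelines=(spec,), n_subjects=200, subject_sd=0.0, seed=77
        )
        cohort = pf.generate_cohort(config)
        mask = cohort.pipeline_masks["a"]
        pooled = []
        for r in range(15):
            rng = np.random.default_rng(1000 + r)
            a = pf.sample_groups(cohort.subject_ids, 50, rng)
            g1 = [cohort[(i, "a")].values for i in a.group1_ids]
            g2 = [cohort[(i, "a")].values for i in a.group2_ids]
            res = pf.two_sample_tmap(g1, g2, mask, "pooled")
            pooled.append(res.t_in_mask())
        t = np.concatenate(pooled)
        ref_sd = np.sqrt(98 / 96)
        # spatial correlation: ~125 effective samples per draw
        assert abs(t.mean()) < 0.12
        assert t.std() == pytest.approx(ref_sd, rel=0.12)
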