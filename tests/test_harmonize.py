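"""Harmonization: spline resampling, mask intersection, unit rescaling."""

import numpy as np
import pytest

import pipefpr as pf
from pipefpr.cohort import PERCENT_BOLD, RAW_UNITS, ContrastMap


def make_map(values, grid, mask=None, units=RAW_UNITS, label="p"):
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return ContrastMap(
        values=values, grid=grid, mask=mask, units=units,
        subject_id=0, pipeline_label=label,
    )


GRID = pf.VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0))


class TestResample:
    def test_identity_grid_returns_input(self, rng):
        cmap = make_map(rng.normal(size=GRID.shape), GRID)
        out = pf.resample_to_template(cmap, GRID)
        np.testing.assert_allclose(out.values, cmap.values, atol=1e-6)
        np.testing.assert_array_equal(out.mask, cmap.mask)

    def test_constant_map_reproduced_in_interior(self):
        shifted = pf.VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0), (0.7, -0.3, 1.1))
        cmap = make_map(np.full(GRID.shape, 3.25), GRID)
        out = pf.resample_to_template(cmap, shifted)
        interior = out.mask
        assert interior.sum() > 1000
        np.testing.assert_allclose(out.values[interior], 3.25, rtol=1e-6)

    def test_half_voxel_shifted_ramp_matches_closed_form(self):
        """Cubic-spline resampling of a linear ramp equals the shifted ramp.

        The spline prefilter's boundary condition perturbs values within a
        few voxels of the volume edge (the error decays geometrically, pole
        ~0.27 per voxel), so the closed-form comparison uses the interior.
        """
        n, rim = 24, 8
        grid = pf.VolumeGrid((n, n, n), (2.0, 2.0, 2.0))
        ramp = np.add.outer(
            np.add.outer(2.0 * np.arange(n), 0.5 * np.arange(n)),
            -1.0 * np.arange(n),
        )  # f(i,j,k) = 2i + 0.5j - k  (per-voxel slopes)
        half = pf.VolumeGrid((n, n, n), (2.0, 2.0, 2.0), (1.0, 0.0, 0.0))
        out = pf.resample_to_template(make_map(ramp, grid), half)
        i, j, k = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        expected = 2.0 * (i + 0.5) + 0.5 * j - 1.0 * k
        inner = out.mask.copy()
        inner[:rim] = inner[n - rim:] = False
        inner[:, :rim] = inner[:, n - rim:] = False
        inner[:, :, :rim] = inner[:, :, n - rim:] = False
        assert inner.sum() >= 500
        np.testing.assert_allclose(out.values[inner], expected[inner], atol=1e-4)

    def test_no_overlap_raises(self):
        far = pf.VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0), (1000.0, 0.0, 0.0))
        cmap = make_map(np.ones(GRID.shape), GRID)
        with pytest.raises(ValueError, match="overlap|empty"):
            pf.resample_to_template(cmap, far)

    def test_out_of_fov_voxels_leave_the_mask(self):
        shifted = pf.VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0), (-6.0, 0.0, 0.0))
        cmap = make_map(np.ones(GRID.shape), GRID)
        out = pf.resample_to_template(cmap, shifted)
        assert not out.mask[:3].any()  # template x<3 maps before source start


class TestIntersectMasks:
    def test_idempotent_on_identical_masks(self, rng):
        m = rng.random(GRID.shape) > 0.3
        np.testing.assert_array_equal(pf.intersect_masks([m, m, m]), m)

    def test_disjoint_masks_error_names_offender(self):
        a = np.zeros(GRID.shape, bool)
        b = np.zeros(GRID.shape, bool)
        a[:8], b[8:] = True, True
        with pytest.raises(ValueError, match="index 1"):
            pf.intersect_masks([a, b])

    def test_nested_masks_give_the_subset(self):
        big = np.ones(GRID.shape, bool)
        small = np.zeros(GRID.shape, bool)
        small[4:12, 4:12, 4:12] = True
        np.testing.assert_array_equal(pf.intersect_masks([big, small]), small)

    def test_monotone_nonincreasing_as_masks_accumulate(self, rng):
        masks = [rng.random(GRID.shape) > 0.2 for _ in range(5)]
        sizes = [
            pf.intersect_masks(masks[: k + 1]).sum() for k in range(len(masks))
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestRescale:
    def test_spm_factor_recovers_percent_bold(self):
        cmap = make_map(np.full(GRID.shape, 250.0), GRID)
        out = pf.rescale(cmap, pf.RescaleRule("SPM-like", 0.4))
        assert out.values[0, 0, 0] == pytest.approx(100.0)
        assert out.units == PERCENT_BOLD

    def test_fsl_factor_recovers_percent_bold(self):
        cmap = make_map(np.full(GRID.shape, 10000.0), GRID)
        out = pf.rescale(cmap, pf.RescaleRule("FSL-like", 0.01))
        assert out.values[0, 0, 0] == pytest.approx(100.0)

    def test_factor_one_is_identity(self, rng):
        cmap = make_map(rng.normal(size=GRID.shape), GRID)
        out = pf.rescale(cmap, pf.RescaleRule("SPM-like", 1.0))
        np.testing.assert_allclose(out.values, cmap.values)

    def test_double_scaling_guard(self):
        cmap = make_map(np.ones(GRID.shape), GRID, units=PERCENT_BOLD)
        with pytest.raises(ValueError, match="already"):
            pf.rescale(cmap, pf.RescaleRule("SPM-like", 0.4))

    def test_default_factors(self):
        assert pf.DEFAULT_RESCALE_FACTORS == {"SPM-like": 0.4, "FSL-like": 0.01}


class TestHarmonizeCohort:
    def test_cross_style_same_subject_ratio_near_one(self, two_style_cohort):
        """Default unit scales cancel exactly after per-style rescaling."""
        result = pf.harmonize_cohort(
            two_style_cohort, two_style_cohort.config.base_grid, pf.default_rules()
        )
        common = result.common_mask
        a = result.maps[(3, "spm-a")].values[common]
        b = result.maps[(3, "fsl-a")].values[common]
        keep = np.abs(b) > 0.05  # avoid near-zero denominators
        np.testing.assert_allclose(a[keep] / b[keep], 1.0, atol=1e-3)

    def test_outputs_are_percent_bold_and_masked(self, two_style_cohort):
        result = pf.harmonize_cohort(
            two_style_cohort, two_style_cohort.config.base_grid, pf.default_rules()
        )
        for cmap in result.maps.values():
            assert cmap.units == PERCENT_BOLD
            assert (cmap.values[~result.common_mask] == 0).all()

    def test_missing_rule_raises(self, two_style_cohort):
        with pytest.raises(KeyError, match="fsl-a"):
            pf.harmonize_cohort(
                two_style_cohort,
                two_style_cohort.config.base_grid,
                {"SPM-like": pf.RescaleRule("SPM-like", 0.4)},
            )

    def test_single_pipeline_identity_with_unit_factor(self, null_cohort):
        maps = {(0, "spm-a"): null_cohort[(0, "spm-a")]}
        result = pf.harmonize_cohort(
            maps,
            null_cohort.config.base_grid,
            {"spm-a": pf.RescaleRule("SPM-like", 1.0)},
        )
        out = result.maps[(0, "spm-a")]
        inside = result.common_mask
        np.testing.assert_allclose(
            out.values[inside], null_cohort[(0, "spm-a")].values[inside], rtol=1e-6
        )
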