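"""Contrast-map harmonization: one grid, one mask, one unit scale.

Maps produced by different software pipelines arrive on different grids
(same 2 mm resolution, different dimensions/origins) and in different unit
conventions. Before any group analysis they are (1) resampled to a common
template grid with third-order spline interpolation, (2) masked with the
intersection of all subject-level brain masks across every pipeline, and
(3) rescaled to percent BOLD change — by 0.4 for SPM-like maps (raw units
are about 2.5x percent BOLD) and 0.01 for FSL-like maps (raw units scaled
to 10,000).

Spline values are never extrapolated: template voxels whose centers fall
outside the source field of view drop out of the resampled mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import PERCENT_BOLD, RAW_UNITS, Cohort, ContrastMap
from .grids import VolumeGrid

__all__ = [
    "RescaleRule",
    "DEFAULT_RESCALE_FACTORS",
    "default_rules",
    "resample_to_template",
    "intersect_masks",
    "rescale",
    "harmonize_cohort",
    "HarmonizedCohort",
]

#: Multiplicative factors that bring raw pipeline units back to percent BOLD
#: change: 100/250 = 0.4 for SPM-like maps, 100/10,000 = 0.01 for FSL-like.
DEFAULT_RESCALE_FACTORS = {"SPM-like": 0.4, "FSL-like": 0.01}


@dataclass(frozen=True)
class RescaleRule:
    software_style: str
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("rescale factor must be > 0")


def default_rules() -> dict[str, RescaleRule]:
    """The standard software-style → rescale-rule mapping."""
    return {
        style: RescaleRule(style, factor)
        for style, factor in DEFAULT_RESCALE_FACTORS.items()
    }


def _inside_fov(src: VolumeGrid, dst: VolumeGrid, tol: float = 1e-9) -> np.ndarray:
    """Template voxels whose centers lie strictly inside the source grid."""
    scale = np.asarray(dst.voxel_size) / np.asarray(src.voxel_size)
    shift = (
        np.asarray(dst.origin_offset) - np.asarray(src.origin_offset)
    ) / np.asarray(src.voxel_size)
    inside = np.ones(dst.shape, dtype=bool)
    for ax in range(3):
        c = np.arange(dst.shape[ax]) * scale[ax] + shift[ax]
        ok = (c >= -tol) & (c <= src.shape[ax] - 1 + tol)
        view = [np.newaxis] * 3
        view[ax] = slice(None)
        inside &= ok[tuple(view)]
    return inside


def resample_to_template(cmap: ContrastMap, template: VolumeGrid) -> ContrastMap:
    """Resample a contrast map onto the template grid.

    Values use third-order spline interpolation (the default continuous
    interpolation of nilearn's resampler); the mask is resampled with
    nearest-neighbour and restricted to voxels strictly inside the source
    field of view, so no spline extrapolation enters downstream statistics.
    """
    if cmap.grid.same_geometry(template):
        return replace(cmap, values=cmap.values.copy(), mask=cmap.mask.copy())
    if not _inside_fov(cmap.grid, template).any():
        raise ValueError(
            f"no overlap between source grid {cmap.grid.shape} and template"
        )
    from nilearn.image import resample_img
    import nibabel as nib

    src_img = nib.Nifti1Image(cmap.values.astype(np.float32), cmap.grid.affine)
    out = resample_img(
        src_img,
        target_affine=template.affine,
        target_shape=template.shape,
        interpolation="continuous",
        fill_value=0.0,
        force_resample=True,
        copy_header=True,
    )
    values = np.asarray(out.dataobj, dtype=np.float32)
    mask_img = nib.Nifti1Image(cmap.mask.astype(np.uint8), cmap.grid.affine)
    mask_out = resample_img(
        mask_img,
        target_affine=template.affine,
        target_shape=template.shape,
        interpolation="nearest",
        fill_value=0,
        force_resample=True,
        copy_header=True,
    )
    mask = np.asarray(mask_out.dataobj) >= 0.5
    mask &= _inside_fov(cmap.grid, template)
    if not mask.any():
        raise ValueError("resampled mask is empty")
    return ContrastMap(
        values=values,
        grid=template,
        mask=mask,
        units=cmap.units,
        subject_id=cmap.subject_id,
        pipeline_label=cmap.pipeline_label,
    )


def intersect_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise AND of brain masks on a common grid; errors if empty."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    out = np.ones(shape, dtype=bool)
    for k, m in enumerate(masks):
        if m.shape != shape:
            raise ValueError(f"mask {k} shape {m.shape} != {shape}")
        out &= m.astype(bool)
        if not out.any():
            raise ValueError(f"mask intersection became empty at mask index {k}")
    return out


def rescale(cmap: ContrastMap, rule: RescaleRule) -> ContrastMap:
    """Multiply raw pipeline units by the rule factor → percent BOLD.

    Refuses maps that are already in percent BOLD (double-scaling guard).
    """
    if cmap.units != RAW_UNITS:
        raise ValueError(
            f"map for subject {cmap.subject_id} / {cmap.pipeline_label!r} is "
            f"already in {cmap.units}; refusing to rescale twice"
        )
    return replace(
        cmap, values=(cmap.values * rule.factor).astype(np.float32), units=PERCENT_BOLD
    )


@dataclass
class HarmonizedCohort:
    """Resampled, masked, rescaled maps plus the common mask and a log."""

    maps: dict[tuple[int, str], ContrastMap]
    common_mask: np.ndarray
    template: VolumeGrid
    log: list[str]


def harmonize_cohort(
    maps: Mapping[tuple[int, str], ContrastMap] | Cohort,
    template: VolumeGrid,
    rules: Mapping[str, RescaleRule],
    *,
    style_of: Mapping[str, str] | None = None,
) -> HarmonizedCohort:
    """Resample → intersect masks → apply common mask → rescale.

    ``rules`` maps either pipeline labels or software styles to
    :class:`RescaleRule`; with style keys, ``style_of`` (label → style) must
    resolve each pipeline. When ``maps`` is a :class:`~pipefpr.cohort.Cohort`
    the styles come from its pipeline specs.
    """
    if isinstance(maps, Cohort):
        style_of = {p.label: p.software_style for p in maps.config.pipelines}
        items = dict(maps.items())
    else:
        items = dict(maps)
    if not items:
        raise ValueError("no maps to harmonize")

    def rule_for(label: str) -> RescaleRule:
        if label in rules:
            return rules[label]
        if style_of and label in style_of and style_of[label] in rules:
            return rules[style_of[label]]
        raise KeyError(f"no rescale rule for pipeline {label!r}")

    for label in {lbl for (_, lbl) in items}:
        rule_for(label)  # fail early on a missing rule

    log: list[str] = []
    resampled = {
        key: resample_to_template(cmap, template) for key, cmap in items.items()
    }
    log.append(f"resampled {len(resampled)} maps to template {template.shape}")
    common = intersect_masks([m.mask for m in resampled.values()])
    log.append(
        f"common mask: {int(common.sum())} voxels "
        f"(intersection of {len(resampled)} subject-level masks)"
    )
    out: dict[tuple[int, str], ContrastMap] = {}
    for key, cmap in resampled.items():
        values = np.where(common, cmap.values, 0.0).astype(np.float32)
        masked = replace(cmap, values=values, mask=common.copy())
        out[key] = rescale(masked, rule_for(cmap.pipeline_label))
    log.append("applied common mask and per-style rescaling")
    return HarmonizedCohort(maps=out, common_mask=common, template=template, log=log)
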