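"""Synthetic multi-pipeline cohort generator.

Emulates a pool of subjects whose task-fMRI contrast maps were produced by
several subject-level analysis "pipelines" (different software conventions,
smoothing kernels, amplitude/gain conventions, bias fields, masks, grids).
Each pipeline is a parametric transform of one shared latent acquisition per
subject, so between-pipeline differences are pure pipeline artifacts — the
statistical structure a between-group validity study needs.

Generative model, per subject ``i`` and pipeline ``p``::

    L_ip  = gain_p * mu + b_i + sqrt(noise_variance_factor_p) * eps_i
    map   = unit_scale_p * [ Smooth(L_ip, smoothing_fwhm_p) + offset_field_p ]

where ``mu`` is the true-effect blob field (percent BOLD), ``b_i`` a scalar
between-subject random effect, and ``eps_i`` Gaussian noise of standard
deviation ``noise_sd`` (white) smoothed to intrinsic FWHM ``noise_fwhm``.
The same ``b_i`` and ``eps_i`` realization underlies all pipelines of a
subject. Smoothing kernels compose in quadrature, so the total output
smoothness is ``sqrt(noise_fwhm**2 + smoothing_fwhm_p**2)`` (see
:func:`total_output_fwhm`). Maps are finally resampled to the pipeline's own
grid when that differs from the base grid.

Randomness: one root seed; subject ``i`` draws from the substream with spawn
key ``(0, i)`` and pipeline ``j``'s bias field from spawn key ``(1, j)``, so
cohorts are bit-reproducible regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import DEFAULT_GRID, VolumeGrid

__all__ = [
    "PipelineSpec",
    "CohortConfig",
    "ContrastMap",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort_manifest",
    "template_brain_mask",
    "total_output_fwhm",
    "config_from_dict",
]

#: Default raw-map unit scale per software style: SPM-like contrast maps come
#: out near 2.5x percent BOLD change, FSL-like maps are scaled to 10,000
#: (100x percent BOLD change).
DEFAULT_UNIT_SCALE = {"SPM-like": 2.5, "FSL-like": 100.0}

RAW_UNITS = "raw_pipeline_units"
PERCENT_BOLD = "percent_BOLD"

_SIGMA_PER_FWHM = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class PipelineSpec:
    """Parametric transform one subject-level pipeline applies.

    ``smoothing_fwhm`` is the Gaussian kernel (mm) the pipeline applies on
    top of the intrinsic noise smoothness. ``gain`` scales the true-effect
    field only (emulating HRF-model / motion-regressor amplitude effects);
    ``offset_field_amplitude`` is the SD (percent BOLD) of a smooth additive
    pipeline bias field shared by all subjects of the pipeline.
    """

    label: str
    software_style: str = "SPM-like"
    smoothing_fwhm: float = 7.0
    unit_scale: float | None = None
    gain: float = 1.0
    offset_field_amplitude: float = 0.0
    noise_variance_factor: float = 1.0
    grid: VolumeGrid = DEFAULT_GRID
    mask_erosion: int = 0

    def __post_init__(self) -> None:
        if self.software_style not in DEFAULT_UNIT_SCALE:
            raise ValueError(
                f"software_style must be one of {sorted(DEFAULT_UNIT_SCALE)}, "
                f"got {self.software_style!r}"
            )
        if self.unit_scale is None:
            object.__setattr__(
                self, "unit_scale", DEFAULT_UNIT_SCALE[self.software_style]
            )
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")
        if self.unit_scale <= 0:
            raise ValueError("unit_scale must be > 0")
        if self.noise_variance_factor <= 0:
            raise ValueError("noise_variance_factor must be > 0")
        if self.mask_erosion < 0:
            raise ValueError("mask_erosion must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the structure of a large openly shared multi-pipeline
    dataset: a pool of 1,080 subjects, contrast maps in percent BOLD change
    with focal task activation of order 1% BOLD, between-subject SD 0.25%
    BOLD, and spatially correlated noise.
    """

    pipelines: tuple[PipelineSpec, ...]
    n_subjects: int = 1080
    #: (center voxel, radius mm (half width at half max), amplitude %BOLD)
    true_effect_blobs: tuple[tuple[tuple[int, int, int], float, float], ...] = (
        ((12, 16, 16), 8.0, 1.0),
        ((22, 17, 20), 6.0, 0.8),
    )
    subject_sd: float = 0.25
    noise_sd: float = 4.0
    noise_fwhm: float = 4.0
    base_grid: VolumeGrid = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pipelines", tuple(self.pipelines))
        object.__setattr__(
            self,
            "true_effect_blobs",
            tuple(
                (tuple(int(c) for c in ctr), float(r), float(a))
                for ctr, r, a in self.true_effect_blobs
            ),
        )
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not self.pipelines:
            raise ValueError("at least one PipelineSpec is required")
        labels = [p.label for p in self.pipelines]
        if len(set(labels)) != len(labels):
            raise ValueError("pipeline labels must be unique")

    def pipeline(self, label: str) -> PipelineSpec:
        for p in self.pipelines:
            if p.label == label:
                return p
        raise KeyError(f"no pipeline labelled {label!r}")


@dataclass
class ContrastMap:
    """One subject's 3D contrast volume with geometry, units, and mask."""

    values: np.ndarray
    grid: VolumeGrid
    mask: np.ndarray
    units: str
    subject_id: int
    pipeline_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must share a shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite values inside mask")


class Cohort(Mapping):
    """Immutable collection of contrast maps indexed by (subject_id, label)."""

    def __init__(
        self,
        maps: dict[tuple[int, str], ContrastMap],
        config: CohortConfig,
        pipeline_masks: dict[str, np.ndarray],
    ) -> None:
        self._maps = maps
        self.config = config
        self.pipeline_masks = pipeline_masks

    def __getitem__(self, key: tuple[int, str]) -> ContrastMap:
        return self._maps[key]

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self._maps)

    def __len__(self) -> int:
        return len(self._maps)

    @property
    def subject_ids(self) -> list[int]:
        return list(range(self.config.n_subjects))

    @property
    def pipeline_labels(self) -> list[str]:
        return [p.label for p in self.config.pipelines]


def total_output_fwhm(spec: PipelineSpec, config: CohortConfig) -> float:
    """Total smoothness (mm) of the generated map: kernels add in quadrature."""
    return math.hypot(config.noise_fwhm, spec.smoothing_fwhm)


def template_brain_mask(grid: VolumeGrid, exponent: float = 2.5) -> np.ndarray:
    """Super-ellipsoid "brain" mask centered on the grid.

    Semi-axes are 3/4 of the half field of view (slightly flattened along z),
    giving an interior region that keeps smoothing edge effects away from the
    volume boundary while still exercising mask-handling code.
    """
    shape = np.asarray(grid.shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = shape / 2.0 * np.array([0.75, 0.75, 0.70])
    coords = np.meshgrid(*(np.arange(int(s)) for s in grid.shape), indexing="ij")
    r = sum(
        (np.abs(c - c0) / a) ** exponent for c, c0, a in zip(coords, center, semi)
    )
    return r <= 1.0


def _blob_field(config: CohortConfig) -> np.ndarray:
    """True-effect field mu: sum of Gaussian-profile blobs (percent BOLD).

    Each blob's radius is its half width at half maximum, so the profile is
    amplitude * exp(-ln2 * (d/radius)^2) with d the world distance (mm) to
    the blob's center voxel.
    """
    grid = config.base_grid
    mu = np.zeros(grid.shape, dtype=np.float64)
    vx = np.asarray(grid.voxel_size)
    coords = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    for center, radius_mm, amplitude in config.true_effect_blobs:
        d2 = sum(
            ((c - c0) * v) ** 2 for c, c0, v in zip(coords, center, vx)
        )
        mu += amplitude * np.exp(-math.log(2.0) * d2 / radius_mm**2)
    return mu


def _smooth(vol: np.ndarray, fwhm_mm: float, voxel_size: Sequence[float]) -> np.ndarray:
    """Gaussian-smooth a volume to kernel FWHM given in mm (reflect edges)."""
    if fwhm_mm <= 0:
        return vol
    sigmas = [fwhm_mm * _SIGMA_PER_FWHM / v for v in voxel_size]
    return ndimage.gaussian_filter(vol, sigmas, mode="reflect")


def _subject_rng(config: CohortConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0, subject_index))
    )


def _pipeline_rng(config: CohortConfig, pipeline_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, pipeline_index))
    )


def _offset_field(
    spec: PipelineSpec, config: CohortConfig, pipeline_index: int
) -> np.ndarray:
    """Smooth additive pipeline bias field, unit SD times the amplitude."""
    grid = config.base_grid
    if spec.offset_field_amplitude == 0.0:
        return np.zeros(grid.shape)
    rng = _pipeline_rng(config, pipeline_index)
    raw = rng.standard_normal(grid.shape)
    # heavily smoothed (1/4 of the field of view) so the bias is low-frequency
    fwhm = 0.25 * min(s * v for s, v in zip(grid.shape, grid.voxel_size))
    smooth = _smooth(raw, fwhm, grid.voxel_size)
    smooth /= smooth.std()
    return spec.offset_field_amplitude * smooth


def _resample_like(
    values: np.ndarray, src: VolumeGrid, dst: VolumeGrid, order: int
) -> np.ndarray:
    """Map a volume from grid ``src`` onto grid ``dst`` (cubic spline)."""
    # voxel coords of dst centers expressed in src voxel space (diagonal affines)
    scale = np.asarray(dst.voxel_size) / np.asarray(src.voxel_size)
    shift = (
        np.asarray(dst.origin_offset) - np.asarray(src.origin_offset)
    ) / np.asarray(src.voxel_size)
    coords = np.meshgrid(*(np.arange(s) for s in dst.shape), indexing="ij")
    coords = [c * s + o for c, s, o in zip(coords, scale, shift)]
    return ndimage.map_coordinates(
        values.astype(np.float64), coords, order=order, mode="constant", cval=0.0
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full multi-pipeline cohort, deterministic given the seed.

    Returns
    -------
    Cohort
        Maps indexed by ``(subject_id, pipeline_label)`` in raw pipeline
        units, plus one eroded brain mask per pipeline.
    """
    base = config.base_grid
    mu = _blob_field(config)
    template_mask = template_brain_mask(base)

    pipeline_masks: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    for j, spec in enumerate(config.pipelines):
        m = template_mask
        if spec.mask_erosion > 0:
            m = ndimage.binary_erosion(m, iterations=spec.mask_erosion)
        if not spec.grid.same_geometry(base):
            m = _resample_like(m.astype(np.float64), base, spec.grid, order=0) >= 0.5
        if not m.any():
            raise ValueError(f"pipeline {spec.label!r}: erosion emptied the mask")
        pipeline_masks[spec.label] = m
        offsets[spec.label] = _offset_field(spec, config, j)

    maps: dict[tuple[int, str], ContrastMap] = {}
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        b_i = rng.normal(0.0, config.subject_sd) if config.subject_sd > 0 else 0.0
        eps = rng.standard_normal(base.shape) * config.noise_sd
        eps = _smooth(eps, config.noise_fwhm, base.voxel_size)
        for spec in config.pipelines:
            latent = (
                spec.gain * mu
                + b_i
                + math.sqrt(spec.noise_variance_factor) * eps
            )
            vol = _smooth(latent, spec.smoothing_fwhm, base.voxel_size)
            vol = vol + offsets[spec.label]
            vol *= spec.unit_scale
            if not spec.grid.same_geometry(base):
                vol = _resample_like(vol, base, spec.grid, order=3)
            maps[(i, spec.label)] = ContrastMap(
                values=vol.astype(np.float32),
                grid=spec.grid,
                mask=pipeline_masks[spec.label],
                units=RAW_UNITS,
                subject_id=i,
                pipeline_label=spec.label,
            )
    return Cohort(maps, config, pipeline_masks)


# ---------------------------------------------------------------------------
# NIfTI round trip


def _nifti_image(values: np.ndarray, grid: VolumeGrid):
    import nibabel as nib

    return nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)


def write_cohort(cohort: Cohort, directory: str | Path) -> pd.DataFrame:
    """Write one .nii.gz per (subject, pipeline) plus per-pipeline masks.

    Returns the manifest table (subject_id, pipeline_label, path), also
    written to ``manifest.csv`` in the output directory.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in cohort.pipeline_labels:
        spec = cohort.config.pipeline(label)
        mask_path = directory / f"mask_{label}.nii.gz"
        nib.save(
            nib.Nifti1Image(
                cohort.pipeline_masks[label].astype(np.uint8), spec.grid.affine
            ),
            mask_path,
        )
    for (sid, label), cmap in cohort.items():
        path = directory / f"sub-{sid:04d}_{label}.nii.gz"
        nib.save(_nifti_image(cmap.values, cmap.grid), path)
        rows.append({"subject_id": sid, "pipeline_label": label, "path": str(path)})
    manifest = pd.DataFrame(rows, columns=["subject_id", "pipeline_label", "path"])
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_cohort_manifest(manifest_path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(manifest_path)
    expected = {"subject_id", "pipeline_label", "path"}
    if not expected.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(expected)}")
    return manifest


# ---------------------------------------------------------------------------
# Config files


def config_from_dict(raw: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML/JSON-loaded) dictionary."""
    raw = dict(raw)
    pipelines = []
    for praw in raw.pop("pipelines"):
        praw = dict(praw)
        if "grid" in praw:
            praw["grid"] = VolumeGrid(**praw["grid"])
        pipelines.append(PipelineSpec(**praw))
    if "base_grid" in raw:
        raw["base_grid"] = VolumeGrid(**raw["base_grid"])
    if "true_effect_blobs" in raw:
        raw["true_effect_blobs"] = tuple(
            (tuple(b[0]), float(b[1]), float(b[2])) for b in raw["true_effect_blobs"]
        )
    return CohortConfig(pipelines=tuple(pipelines), **raw)
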