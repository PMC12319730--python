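"""Voxel-wise one-tailed two-sample t analysis between two groups.

The between-group design under study: sample 100 subjects without
replacement from the pool, split into two groups of 50, take each group's
contrast maps from a (possibly different) pipeline, and test H0 "no mean
difference of activation between groups" voxel by voxel, one-tailed.

Both unequal-variance (Welch, per-voxel Satterthwaite df) and pooled-variance
(df = n1 + n2 - 2; with 50 per group, the T98 reference) modes are exposed:
second-level software packages differ in how they handle nonsphericity, and
the reference null used by the diagnostics is the pooled-df Student law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import ContrastMap

__all__ = ["GroupAssignment", "TStatResult", "sample_groups", "two_sample_tmap"]

DIRECTIONS = ("group1_gt_group2", "group2_gt_group1")


@dataclass(frozen=True)
class GroupAssignment:
    group1_ids: tuple[int, ...]
    group2_ids: tuple[int, ...]
    pipeline1: str
    pipeline2: str

    def __post_init__(self) -> None:
        if set(self.group1_ids) & set(self.group2_ids):
            raise ValueError("groups must be disjoint")


@dataclass
class TStatResult:
    """Voxel-wise two-sample t map with df and standardized residuals.

    ``t_values`` is a full 3D volume, NaN outside ``valid_mask``;
    ``valid_mask`` is the analysis mask minus voxels where the standard
    error degenerated to zero (their count is ``n_undefined``). ``df`` is a
    per-voxel volume in Welch mode and a scalar in pooled mode.
    """

    t_values: np.ndarray
    df: np.ndarray | float
    direction: str
    residual_maps: np.ndarray
    valid_mask: np.ndarray
    n1: int
    n2: int
    n_undefined: int
    variance_mode: str

    @property
    def df_scalar(self) -> float:
        """Scalar df summary: pooled df, or the median Satterthwaite df."""
        if np.isscalar(self.df) or np.ndim(self.df) == 0:
            return float(self.df)
        return float(np.median(np.asarray(self.df)[self.valid_mask]))

    def t_in_mask(self) -> np.ndarray:
        return self.t_values[self.valid_mask]


def sample_groups(
    pool: Sequence[int],
    n_per_group: int,
    rng: np.random.Generator,
    pipeline1: str = "",
    pipeline2: str = "",
) -> GroupAssignment:
    """Draw 2*n distinct subjects uniformly without replacement; first half
    becomes group 1."""
    pool = np.asarray(pool)
    if pool.size < 2 * n_per_group:
        raise ValueError(
            f"pool of {pool.size} subjects cannot supply 2x{n_per_group}"
        )
    drawn = rng.choice(pool, size=2 * n_per_group, replace=False)
    return GroupAssignment(
        group1_ids=tuple(int(i) for i in drawn[:n_per_group]),
        group2_ids=tuple(int(i) for i in drawn[n_per_group:]),
        pipeline1=pipeline1,
        pipeline2=pipeline2,
    )


def _stack(maps: Sequence[ContrastMap | np.ndarray]) -> np.ndarray:
    vols = [
        m.values if isinstance(m, ContrastMap) else np.asarray(m) for m in maps
    ]
    return np.stack([np.asarray(v, dtype=np.float64) for v in vols], axis=0)


def two_sample_tmap(
    group1_maps: Sequence[ContrastMap | np.ndarray],
    group2_maps: Sequence[ContrastMap | np.ndarray],
    mask: np.ndarray,
    variance_mode: str = "welch",
    direction: str = "group1_gt_group2",
) -> TStatResult:
    """Per-voxel two-sample t statistic (group1 - group2, optionally negated).

    Residual maps are per-subject ``(value - group mean) / group sd``
    volumes (both groups stacked), the input the smoothness estimator needs.
    Voxels where both groups have zero variance are flagged and removed from
    ``valid_mask`` rather than zero-filled.
    """
    if variance_mode not in ("welch", "pooled"):
        raise ValueError("variance_mode must be 'welch' or 'pooled'")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if len(group1_maps) < 2 or len(group2_maps) < 2:
        raise ValueError("need at least two maps per group")
    x1 = _stack(group1_maps)
    x2 = _stack(group2_maps)
    n1, n2 = x1.shape[0], x2.shape[0]
    mask = np.asarray(mask, dtype=bool)

    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if variance_mode == "welch":
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = float(n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(se2)

    defined = mask & np.isfinite(t)
    n_undefined = int(mask.sum() - defined.sum())
    t = np.where(defined, t, np.nan)
    if direction == "group2_gt_group1":
        t = -t

    s1 = np.sqrt(v1)
    s2 = np.sqrt(v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(s1 > 0, (x1 - m1) / s1, 0.0)
        r2 = np.where(s2 > 0, (x2 - m2) / s2, 0.0)
    residuals = np.concatenate([r1, r2], axis=0).astype(np.float32)

    return TStatResult(
        t_values=t,
        df=df if variance_mode == "welch" else float(df),
        direction=direction,
        residual_maps=residuals,
        valid_mask=defined,
        n1=n1,
        n2=n2,
        n_undefined=n_undefined,
        variance_mode=variance_mode,
    )
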