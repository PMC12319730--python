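"""Distributional diagnostics: Bland–Altman P-P curves and t-value summaries.

Under the null, one-tailed p-values of the pooled voxel statistics are
Uniform(0, 1), so the k-th of N ordered p-values follows Beta(k, N-k+1)
with expected value k/(N+1). The Bland–Altman variant of the P-P plot puts
-log10 of the expected p-value on the x axis and the difference between
-log10 observed and -log10 expected p-values on the y axis, with pointwise
95% bands from Beta quantiles. A curve escaping above the band signals
invalidity (p-values too small too often); below, conservativeness.

The Beta bands assume independent p-values; spatially correlated voxel
statistics violate that, so a thinning stride (default every 100th voxel)
is applied when pooling statistics from t maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import TStatResult

__all__ = [
    "PPCurve",
    "pvalues_from_tmaps",
    "pp_bland_altman",
    "stat_distribution_report",
]

#: Smallest p-value admitted before the -log10 transform.
P_FLOOR = 1e-300


@dataclass
class PPCurve:
    """Ordered p-values vs. uniform order statistics, Bland–Altman axes."""

    N: int
    k: np.ndarray
    expected_p: np.ndarray
    observed_p: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lower_band: np.ndarray
    upper_band: np.ndarray
    band_level: float
    n_floored: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "expected_p": self.expected_p,
                "observed_p": self.observed_p,
                "x": self.x,
                "y": self.y,
                "lo": self.lower_band,
                "hi": self.upper_band,
            }
        )

    def fraction_inside_bands(self) -> float:
        inside = (self.y >= self.lower_band) & (self.y <= self.upper_band)
        return float(inside.mean())


def pvalues_from_tmaps(
    t_records: Iterable[TStatResult | np.ndarray],
    df_reference: float = 98.0,
    stride: int = 100,
) -> np.ndarray:
    """One-tailed upper p-values of pooled voxel statistics.

    Statistics are pooled across repetitions and thinned to every
    ``stride``-th value (in pooling order) to reduce the spatial dependence
    the Beta bands do not model. ``df_reference`` defaults to 98, the
    pooled-variance df of a 50-vs-50 comparison.
    """
    if df_reference <= 0:
        raise ValueError("df_reference must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    chunks = []
    for rec in t_records:
        t = rec.t_in_mask() if isinstance(rec, TStatResult) else np.asarray(rec).ravel()
        chunks.append(t[np.isfinite(t)])
    if not chunks:
        raise ValueError("no t records supplied")
    pooled = np.concatenate(chunks)[::stride]
    return stats.t.sf(pooled, df_reference)


def pp_bland_altman(pvalues: Sequence[float], band_level: float = 0.95) -> PPCurve:
    """Build the Bland–Altman P-P curve with Beta order-statistic bands.

    Exact zeros are floored at ``P_FLOOR`` before the log transform and
    counted in ``n_floored``.
    """
    if not 0.0 < band_level < 1.0:
        raise ValueError("band_level must be in (0, 1)")
    p = np.sort(np.asarray(pvalues, dtype=np.float64))
    n = p.size
    if n < 10:
        raise ValueError(f"need at least 10 p-values, got {n}")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n_floored = int((p < P_FLOOR).sum())
    p = np.maximum(p, P_FLOOR)

    k = np.arange(1, n + 1)
    expected = k / (n + 1.0)
    x = -np.log10(expected)
    y = -np.log10(p) - x

    tail = (1.0 - band_level) / 2.0
    q_lo = stats.beta.ppf(tail, k, n - k + 1)
    q_hi = stats.beta.ppf(1.0 - tail, k, n - k + 1)
    # small p ↔ large -log10 p: the upper y band comes from the lower
    # Beta quantile and vice versa
    upper = -np.log10(np.maximum(q_lo, P_FLOOR)) - x
    lower = -np.log10(np.maximum(q_hi, P_FLOOR)) - x
    return PPCurve(
        N=n,
        k=k,
        expected_p=expected,
        observed_p=p,
        x=x,
        y=y,
        lower_band=lower,
        upper_band=upper,
        band_level=band_level,
        n_floored=n_floored,
    )


def stat_distribution_report(
    t_values: Sequence[float] | np.ndarray,
    df_reference: float = 98.0,
    n_bins: int = 80,
) -> dict:
    """Moments of pooled t values against the Student reference.

    Flags a mean shift when |mean| exceeds 3 standard errors and a variance
    shift when the SD ratio to the reference leaves [0.9, 1.1]. Histogram
    counts (density-normalized) and the reference density at bin centers are
    included for plotting.
    """
    t = np.asarray(t_values, dtype=np.float64).ravel()
    t = t[np.isfinite(t)]
    if t.size < 1000:
        raise ValueError("need >= 1000 pooled statistic values")
    v = float(df_reference)
    ref_sd = math.sqrt(v / (v - 2.0)) if v > 2 else float("inf")
    mean = float(t.mean())
    sd = float(t.std(ddof=1))
    se_mean = ref_sd / math.sqrt(t.size)
    counts, edges = np.histogram(t, bins=n_bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    sd_ratio = sd / ref_sd
    return {
        "n": int(t.size),
        "mean": mean,
        "sd": sd,
        "skewness": float(stats.skew(t)),
        "ref_mean": 0.0,
        "ref_sd": ref_sd,
        "sd_ratio": sd_ratio,
        "mean_shift_flag": bool(abs(mean) > 3.0 * se_mean),
        "variance_shift_flag": bool(sd_ratio < 0.9 or sd_ratio > 1.1),
        "histogram": {
            "bin_centers": centers,
            "density": counts,
            "ref_density": stats.t.pdf(centers, v),
        },
    }
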