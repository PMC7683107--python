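"""First-order (intensity histogram) features, standard radiomics definitions.

Eighteen features of the raw ROI intensity distribution. ``Entropy`` and
``Uniformity`` are computed on the discretized histogram (the same gray-level
binning the texture matrices use); all others operate on the continuous
values. Percentiles use linear interpolation. Skewness and Kurtosis of a
constant ROI are defined as 0; Kurtosis is *not* excess kurtosis (a Gaussian
scores ~3).
"""

from __future__ import annotations

import numpy as np

from ..image import ImageSlice, ROIMask
from .discretize import DiscretizationConfig, discretize

__all__ = ["FIRST_ORDER_NAMES", "first_order_features"]

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    image: ImageSlice, mask: ROIMask, config: DiscretizationConfig | None = None
) -> dict[str, float]:
    mask.require_nonempty()
    mask.require_aligned(image)
    v = image.values[mask.mask].astype(float)
    n = v.size
    pixel_area = image.spacing[0] * image.spacing[1]

    mean = v.mean()
    centered = v - mean
    m2 = np.mean(centered**2)
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]

    levels, _ = discretize(image.values, mask.mask, config)
    counts = np.bincount(levels[mask.mask])[1:]
    p = counts[counts > 0] / n

    out = {
        "Energy": float(np.sum(v**2)),
        "TotalEnergy": float(pixel_area * np.sum(v**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Skewness": float(np.mean(centered**3) / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(np.mean(centered**4) / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
    return out
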