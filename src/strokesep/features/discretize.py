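"""Gray-level discretization of ROI intensities.

All second-order texture matrices (co-occurrence, run-length, size-zone,
dependence, tone-difference) operate on integer gray levels 1..Ng obtained by
binning the continuous attenuation values inside the ROI. Two standard modes
are supported: a fixed bin width in intensity units (robust to ROI-size
differences, the default at 5 HU) and a fixed number of equal-width bins
spanning the ROI's intensity range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["DiscretizationConfig", "discretize"]


@dataclass(frozen=True)
class DiscretizationConfig:
    mode: str = "fixed_bin_width"  # or "fixed_bin_count"
    bin_width: float = 5.0
    bin_count: int = 32

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_width", "fixed_bin_count"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.bin_width <= 0 or self.bin_count <= 0:
            raise ValueError("bin width and bin count must be positive")


def discretize(
    values: np.ndarray, mask: np.ndarray, config: DiscretizationConfig | None = None
) -> tuple[np.ndarray, int]:
    """Map ROI intensities to integer gray levels.

    Returns ``(levels, n_levels)`` where ``levels`` has the shape of the
    input, holds levels ``1..Ng`` inside the mask and 0 outside. With fixed
    bin width w: ``level = floor((v - min) / w) + 1``. With fixed bin count k:
    k equal-width bins over [min, max] inside the ROI, the maximum assigned to
    bin k. A constant ROI collapses to a single level (logged).
    """
    config = config if config is not None else DiscretizationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    v = np.asarray(values, dtype=float)
    roi = v[mask]
    vmin, vmax = roi.min(), roi.max()
    levels = np.zeros(v.shape, dtype=np.int64)
    if vmax == vmin:
        log.debug("constant ROI: discretization collapses to a single gray level")
        levels[mask] = 1
        return levels, 1
    if config.mode == "fixed_bin_width":
        lv = np.floor((roi - vmin) / config.bin_width).astype(np.int64) + 1
    else:
        width = (vmax - vmin) / config.bin_count
        lv = np.minimum(np.floor((roi - vmin) / width).astype(np.int64) + 1, config.bin_count)
    levels[mask] = lv
    return levels, int(lv.max())
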