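"""Nonlinear image transforms feeding the high-throughput feature bank.

Each feature class is computed not only on the original slice but on a set of
transformed copies: single-level 2D wavelet subbands, pointwise nonlinearities
(square, square root, logarithm, exponential) and the gradient magnitude.

CT attenuation is negative over much of its range, so pointwise
nonlinearities are applied after shifting intensities to be >= 1 inside the
ROI (``v' = v - min(ROI) + 1``), and their outputs are rescaled linearly back
to the ROI's original intensity range. The rescaling keeps a fixed-bin-width
discretization meaningful across transforms (an unrescaled exponential would
produce astronomically many gray levels) while preserving the intensity
*ordering* the nonlinearity imposes.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..image import ImageSlice, ROIMask

__all__ = ["TRANSFORM_KINDS", "apply_transform"]

TRANSFORM_KINDS = (
    "original",
    "wavelet_LL",
    "wavelet_LH",
    "wavelet_HL",
    "wavelet_HH",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
    "gradient",
)

_WAVELET = "haar"


def _rescale_to_roi_range(t: np.ndarray, roi: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    tmin, tmax = t[roi].min(), t[roi].max()
    if tmax == tmin:
        return np.full_like(t, vmin)
    return vmin + (t - tmin) * (vmax - vmin) / (tmax - tmin)


def _wavelet_subband(values: np.ndarray, which: str) -> np.ndarray:
    """Single-level stationary (undecimated) 2D wavelet subband.

    The stationary transform is shift-invariant: a region and its mirrored
    counterpart see identical subband statistics regardless of where they sit
    on the pixel grid. A decimated DWT would tie the subbands to the parity
    of the 2x2 downsampling grid and systematically distinguish reflected
    regions from originals.
    """
    h, w = values.shape
    ph, pw = h % 2, w % 2  # swt2 needs even extents; pad then crop
    padded = np.pad(values, ((0, ph), (0, pw)), mode="symmetric")
    (ll, (lh, hl, hh)), = pywt.swt2(padded, _WAVELET, level=1, norm=True)
    band = {"LL": ll, "LH": lh, "HL": hl, "HH": hh}[which]
    return band[:h, :w]


def apply_transform(image: ImageSlice, mask: ROIMask, kind: str) -> ImageSlice:
    """Return the transformed slice for one of :data:`TRANSFORM_KINDS`.

    Deterministic; the mask only supplies the ROI intensity statistics used
    for shifting/rescaling the pointwise nonlinearities.
    """
    if kind not in TRANSFORM_KINDS:
        raise ValueError(f"unknown transform kind {kind!r}")
    mask.require_nonempty()
    mask.require_aligned(image)
    v = image.values
    roi = mask.mask

    if kind == "original":
        return ImageSlice(v.copy(), image.spacing)
    if kind.startswith("wavelet_"):
        return ImageSlice(_wavelet_subband(v, kind.split("_")[1]), image.spacing)
    if kind == "gradient":
        gr, gc = np.gradient(v)
        return ImageSlice(np.hypot(gr, gc), image.spacing)

    vmin, vmax = v[roi].min(), v[roi].max()
    shifted = np.clip(v - vmin + 1.0, 1.0, None)
    if kind == "square":
        t = shifted**2
    elif kind == "squareroot":
        t = np.sqrt(shifted)
    elif kind == "logarithm":
        t = np.log(shifted)
    else:  # exponential
        smax = shifted[roi].max()
        t = np.exp(shifted / smax)
    return ImageSlice(_rescale_to_roi_range(t, roi, vmin, vmax), image.spacing)
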