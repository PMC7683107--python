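"""Core 2D image containers.

Everything downstream works on axial CT-like slices: a rectangular grid of
attenuation values in Hounsfield units (HU) with an in-plane pixel spacing,
plus binary region-of-interest masks aligned to such a slice. Coordinates are
row-major, 0-based; the image "center" used by all geometric operations is
``((H - 1) / 2, (W - 1) / 2)`` so that a width-W image is mirror-symmetric
about the column axis exactly when ``values == values[:, ::-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageSlice", "ROIMask", "bounding_box"]


@dataclass(frozen=True)
class ImageSlice:
    """A single axial slice: 2D attenuation grid (HU) plus pixel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError(f"slice must be a nonempty 2D grid, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("slice contains non-finite attenuation values")
        if len(self.spacing) != 2 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"pixel spacing must be two positive lengths, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def center(self) -> tuple[float, float]:
        """Geometric center in (row, col) pixel coordinates."""
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


@dataclass(frozen=True)
class ROIMask:
    """Binary mask aligned to a companion :class:`ImageSlice`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError(f"mask must be a nonempty 2D grid, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> None:
        if self.area == 0:
            raise ValueError("ROI mask has no foreground pixels")

    def require_aligned(self, image: ImageSlice) -> None:
        if self.shape != image.shape:
            raise ValueError(f"mask shape {self.shape} does not match slice shape {image.shape}")

    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        if rows.size == 0:
            raise ValueError("centroid of an empty mask is undefined")
        return (float(rows.mean()), float(cols.mean()))


def bounding_box(mask: np.ndarray, pad: int = 0) -> tuple[slice, slice]:
    """Tight bounding box of a boolean mask, expanded by ``pad`` pixels and
    clipped to the array bounds."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("bounding box of an empty mask is undefined")
    r0 = max(int(rows.min()) - pad, 0)
    r1 = min(int(rows.max()) + 1 + pad, mask.shape[0])
    c0 = max(int(cols.min()) - pad, 0)
    c1 = min(int(cols.max()) + 1 + pad, mask.shape[1])
    return (slice(r0, r1), slice(c0, c1))
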