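"""The feature registry and per-region extraction driver.

The bank is the cross product of image transforms and feature classes:
10 transforms x (18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
5 NGTDM) = 930 named features by default. Names follow
``<transform>_<class>_<feature>``, e.g.
``square_glrlm_ShortRunLowGrayLevelEmphasis``.

Transforms and matrices are computed on the ROI bounding box padded by a few
pixels (default 8), which localizes the wavelet/gradient context to the
region; features therefore depend only on pixels near the mask. Non-finite
feature values are replaced by 0 and logged so the table stays rectangular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..image import ImageSlice, ROIMask, bounding_box
from .discretize import DiscretizationConfig, discretize
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .glcm import GLCM_NAMES, glcm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .texture import GLDM_NAMES, GLSZM_NAMES, NGTDM_NAMES, gldm_features, glszm_features, ngtdm_features
from .transforms import TRANSFORM_KINDS, apply_transform

log = logging.getLogger(__name__)

__all__ = ["ExtractionConfig", "feature_registry", "extract_all"]

FEATURE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

_CLASS_NAMES = {
    "firstorder": FIRST_ORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


@dataclass(frozen=True)
class ExtractionConfig:
    transforms: tuple[str, ...] = TRANSFORM_KINDS
    classes: tuple[str, ...] = FEATURE_CLASSES
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    padding: int = 8
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        for t in self.transforms:
            if t not in TRANSFORM_KINDS:
                raise ValueError(f"unknown transform {t!r}")
        for c in self.classes:
            if c not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {c!r}")


def feature_registry(config: ExtractionConfig | None = None) -> list[str]:
    """The ordered list of feature names the given configuration produces."""
    config = config if config is not None else ExtractionConfig()
    return [
        f"{t}_{c}_{name}"
        for t in config.transforms
        for c in config.classes
        for name in _CLASS_NAMES[c]
    ]


def extract_all(
    image: ImageSlice, mask: ROIMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract the full named feature vector for one candidate region.

    The vector has the exact length and ordering of
    :func:`feature_registry`; failures of individual features are logged and
    reported as 0 rather than aborting the region.
    """
    config = config if config is not None else ExtractionConfig()
    mask.require_nonempty()
    mask.require_aligned(image)

    rows, cols = bounding_box(mask.mask, pad=config.padding)
    sub_img = ImageSlice(image.values[rows, cols], image.spacing)
    sub_mask = ROIMask(mask.mask[rows, cols])

    out: dict[str, float] = {}
    for t in config.transforms:
        timg = apply_transform(sub_img, sub_mask, t)
        levels, _ = discretize(timg.values, sub_mask.mask, config.discretization)
        for c in config.classes:
            try:
                vals = _compute_class(c, timg, sub_mask, levels, config)
            except Exception:  # pragma: no cover - defensive
                log.exception("feature class %s failed on transform %s", c, t)
                vals = {name: 0.0 for name in _CLASS_NAMES[c]}
            for name in _CLASS_NAMES[c]:
                v = vals[name]
                if not np.isfinite(v):
                    log.warning("non-finite value for %s_%s_%s replaced by 0", t, c, name)
                    v = 0.0
                out[f"{t}_{c}_{name}"] = float(v)
    return out


def _compute_class(c, timg, sub_mask, levels, config):
    if c == "firstorder":
        return first_order_features(timg, sub_mask, config.discretization)
    if c == "glcm":
        return glcm_features(levels, sub_mask.mask, config.distances, config.angles)
    if c == "glrlm":
        return glrlm_features(levels, sub_mask.mask, config.angles)
    if c == "glszm":
        return glszm_features(levels, sub_mask.mask)
    if c == "gldm":
        return gldm_features(levels, sub_mask.mask)
    return ngtdm_features(levels, sub_mask.mask)
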