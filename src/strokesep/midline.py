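"""Brain midline estimation and contralateral ROI mirroring.

The healthy brain is roughly mirror-symmetric about its midsagittal line, so
the natural internal control for a candidate lesion region is the
corresponding region in the opposite hemisphere. This module estimates the
midline of a slice by maximizing the correlation between the brain-masked
image and its reflection across a candidate line, then reflects ROI masks
across that line to build (region, mirrored region) candidate pairs.

A midline is parameterized by ``(offset, angle)``: the line passes through
``(center_row, center_col + offset)`` at ``angle`` degrees from vertical
(positive angle tilts toward increasing columns as rows increase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageSlice, ROIMask
from .phantom import SyntheticSubject

log = logging.getLogger(__name__)

__all__ = [
    "MidlineParams",
    "CandidateRegion",
    "reflection_matrix",
    "estimate_midline",
    "mirror_roi",
    "make_candidate_pairs",
]


@dataclass(frozen=True)
class MidlineParams:
    offset: float = 0.0  # px, signed column offset from the image center
    angle: float = 0.0  # degrees from vertical

    def __post_init__(self) -> None:
        if abs(self.angle) > 30:
            raise ValueError("midline angle outside the plausible +/-30 degree range")


@dataclass(frozen=True)
class CandidateRegion:
    """The unit of classification: one ROI on one slice with a side label."""

    image: ImageSlice
    mask: ROIMask
    label: str  # lesion | mirror | normal | normal_mirror
    subject_id: str
    pair_id: str


def reflection_matrix(midline: MidlineParams, shape: tuple[int, int]) -> np.ndarray:
    """3x3 involutive matrix reflecting (row, col, 1) points across the line."""
    h, w = shape
    p0 = np.array([(h - 1) / 2.0, (w - 1) / 2.0 + midline.offset])
    a = np.deg2rad(midline.angle)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    flip = np.diag([1.0, -1.0])  # reflect the column coordinate
    lin = rot @ flip @ rot.T
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = p0 - lin @ p0
    return m


def _reflect_array(arr: np.ndarray, midline: MidlineParams, order: int) -> np.ndarray:
    m = reflection_matrix(midline, arr.shape)
    # a reflection is its own inverse, so the sampling map is m itself
    return ndimage.affine_transform(
        arr.astype(float), m[:2, :2], offset=m[:2, 2], order=order,
        mode="constant", cval=float(arr.min()) if order > 0 else 0.0,
    )


def _symmetry_score(values: np.ndarray, brain: np.ndarray, midline: MidlineParams) -> float:
    reflected = _reflect_array(values, midline, order=1)
    rbrain = _reflect_array(brain.astype(float), midline, order=0) > 0.5
    valid = brain & rbrain
    if valid.sum() < 100:
        return -np.inf
    a = values[valid]
    b = reflected[valid]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def estimate_midline(
    image: ImageSlice,
    brain_mask: ROIMask,
    offset_range: float = 20.0,
    angle_range: float = 10.0,
    offset_step: float = 1.0,
    angle_step: float = 0.5,
    downsample: int = 2,
) -> MidlineParams:
    """Reflection-correlation grid search for the symmetry axis.

    A coarse pass (2 px / 2 deg) on a ``downsample``-decimated image brackets
    the optimum; a fine pass refines it to ``offset_step`` / ``angle_step``.
    Ties break toward the smallest |angle|, then smallest |offset|.
    """
    brain_mask.require_aligned(image)
    if brain_mask.area < 100:
        raise ValueError("brain mask too small to estimate a midline")
    ds = max(1, int(downsample))

    c_col = (image.shape[1] - 1) / 2.0

    def search(offsets: np.ndarray, angles: np.ndarray, step: int) -> tuple[float, float]:
        values = image.values[::step, ::step]
        brain = brain_mask.mask[::step, ::step]
        # decimated pixel i sits at original column i*step, so the original
        # axis at column c_col + o maps to decimated offset below
        c_ds = (values.shape[1] - 1) / 2.0
        cands = [(o, a) for a in angles for o in offsets]
        cands.sort(key=lambda oa: (abs(oa[1]), abs(oa[0]), oa[1], oa[0]))
        best, best_score = (0.0, 0.0), -np.inf
        for o, a in cands:
            o_ds = (c_col + o) / step - c_ds
            score = _symmetry_score(values, brain, MidlineParams(offset=o_ds, angle=a))
            if score > best_score + 1e-12:
                best_score, best = score, (o, a)
        return best

    coarse_off = np.arange(-offset_range, offset_range + 1e-9, 2.0)
    coarse_ang = np.arange(-angle_range, angle_range + 1e-9, 2.0)
    o0, a0 = search(coarse_off, coarse_ang, 2 * ds)
    fine_off = np.arange(o0 - 2.0, o0 + 2.0 + 1e-9, offset_step)
    fine_ang = np.arange(a0 - 2.0, a0 + 2.0 + 1e-9, angle_step)
    fine_ang = fine_ang[np.abs(fine_ang) <= angle_range + 1e-9]
    o1, a1 = search(fine_off, fine_ang, ds)
    return MidlineParams(offset=float(o1), angle=float(a1))


def rerasterize(mask: ROIMask) -> ROIMask:
    """Re-rasterize a mask through the same smooth-and-rank operator that
    :func:`mirror_roi` applies, preserving its area exactly.

    Candidate pairs put the original ROI through this operator so that both
    members of a pair have boundaries of identical character; otherwise the
    subtly different staircase statistics of analytic versus resampled
    outlines let a classifier tell originals from mirrors regardless of any
    lesion.
    """
    mask.require_nonempty()
    flat = ndimage.gaussian_filter(mask.mask.astype(float), 1.0).ravel()
    out = np.zeros(flat.size, dtype=bool)
    order = np.argsort(-flat, kind="stable")
    out[order[: mask.area]] = True
    return ROIMask(out.reshape(mask.shape))


def mirror_roi(mask: ROIMask, midline: MidlineParams) -> ROIMask:
    """Reflect a binary ROI across the midline.

    The mask is sampled through the reflection with linear interpolation and
    binarized by keeping the ``area`` highest-weight pixels, so the mirrored
    region preserves the original area exactly whenever the reflection stays
    inside the image (plain 0.5-thresholding systematically erodes small
    convex masks). Fails if most of the reflection falls outside the image.
    """
    mask.require_nonempty()
    weights = _reflect_array(mask.mask.astype(float), midline, order=1)
    if weights.sum() < 0.5 * mask.area:
        raise ValueError("mirrored ROI left the image")
    # mild smoothing makes the rank-based boundary spatially coherent, so the
    # mirrored outline has the same staircase character as a directly
    # rasterized region (a ragged boundary would imprint a systematic texture
    # difference between originals and mirrors)
    flat = ndimage.gaussian_filter(weights, 1.0).ravel()
    n_keep = min(mask.area, int((flat > 1e-9).sum()))
    out = np.zeros(flat.size, dtype=bool)
    order = np.argsort(-flat, kind="stable")
    out[order[:n_keep]] = True
    return ROIMask(out.reshape(mask.shape))


def make_candidate_pairs(
    subject: SyntheticSubject,
    midlines: list[MidlineParams] | None = None,
    min_brain_fraction: float = 0.5,
) -> list[tuple[CandidateRegion, CandidateRegion]]:
    """Build (region, mirrored region) pairs for every slice of a subject.

    If ``midlines`` is not given, the midline of each slice is estimated from
    the image — the generator's ground-truth axis is never consulted.
    Mirrored masks are clipped to the brain; a pair whose mirror keeps less
    than ``min_brain_fraction`` of its area is dropped with a log message.
    """
    labels = ("lesion", "mirror") if subject.group == "lesion" else ("normal", "normal_mirror")
    pairs = []
    for k, rec in enumerate(subject.slices):
        midline = midlines[k] if midlines is not None else estimate_midline(rec.image, rec.brain)
        try:
            mirrored = mirror_roi(rec.roi, midline)
        except ValueError as exc:
            raise ValueError(f"subject {subject.subject_id}, slice {k}: {exc}") from exc
        clipped = mirrored.mask & rec.brain.mask
        if clipped.sum() < min_brain_fraction * mirrored.area:
            log.warning(
                "subject %s slice %d: mirrored ROI mostly outside the brain, pair dropped",
                subject.subject_id, k,
            )
            continue
        pair_id = f"{subject.subject_id}_s{k}"
        # both members go through the same rasterization operator so that
        # boundary character cannot encode which side a region came from
        original = ROIMask(rerasterize(rec.roi).mask & rec.brain.mask)
        pairs.append(
            (
                CandidateRegion(rec.image, original, labels[0], subject.subject_id, pair_id),
                CandidateRegion(rec.image, ROIMask(clipped), labels[1], subject.subject_id, pair_id),
            )
        )
    return pairs
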