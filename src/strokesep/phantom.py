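"""Synthetic head-CT phantoms and cohorts.

The analysis downstream (symmetric candidate regions, texture radiomics,
information-gain screening, classifier cross-validation) needs CT slices in
which an early ischemic lesion is *nearly invisible*: a few HU of mean
attenuation drop and a loss of local texture, buried in correlated image
noise. This module generates such data with known ground truth:

* :func:`generate_head_slice` — a roughly bilaterally symmetric axial slice:
  elliptical skull ring, white-matter interior, a cortical gray-matter ribbon
  and mirrored deep-gray nuclei, overlaid with spatially correlated Gaussian
  noise and an optional small left/right mean jitter (real brains are not
  perfectly mirror-identical).
* :func:`sample_lesion_roi` — a connected blob-shaped ROI confined to one
  hemisphere.
* :func:`inject_lesion` — lowers the mean attenuation inside the ROI by
  ``delta_hu`` and smooths local texture, with feathered edges.
* :func:`generate_cohort` — lesion subjects contribute one slice each with a
  true lesion ROI; control subjects contribute three slices each, carrying
  lesion-shaped ROIs resampled from the lesion subjects' mask library and
  placed at valid positions inside the control brain (data augmentation by
  label projection).

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import ImageSlice, ROIMask

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "SubjectSlice",
    "SyntheticSubject",
    "generate_head_slice",
    "sample_lesion_roi",
    "inject_lesion",
    "apply_pose",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the noise-free head phantom plus its noise model.

    Tissue means are in HU and must be ordered
    background < white matter < gray matter < skull; defaults are typical
    non-contrast head-CT values (air background, ~25/38 HU white/gray matter,
    dense bone). ``noise_corr_len`` is the Gaussian smoothing scale (pixels)
    applied to the white-noise field, giving the correlated speckle texture
    that second-order features respond to. ``asymmetry_jitter`` is the SD (HU)
    of a random left/right mean perturbation of brain tissue.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_spacing: tuple[float, float] = (0.45, 0.45)
    mean_background: float = -1000.0
    mean_csf: float = 8.0
    mean_white: float = 25.0
    mean_gray: float = 38.0
    mean_skull: float = 700.0
    noise_sd: float = 5.0
    noise_corr_len: float = 1.5
    asymmetry_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2 or any(int(s) <= 0 for s in self.image_shape):
            raise ValueError(f"image_shape must be two positive integers, got {self.image_shape}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (
            self.mean_background < self.mean_csf < self.mean_white < self.mean_gray < self.mean_skull
        ):
            raise ValueError("tissue means must be ordered background < csf < white < gray < skull")


@dataclass(frozen=True)
class LesionSpec:
    """A blob-shaped unilateral lesion with a subtle attenuation/texture effect.

    ``delta_hu`` (non-positive) is the mean attenuation change inside the ROI;
    ``smooth_sigma`` (pixels) is the extra Gaussian smoothing applied inside
    the ROI, modeling the loss of gray-white texture differentiation;
    ``boundary_irregularity`` in [0, 1) controls the raggedness of the blob
    outline (0 gives an exact disk of radius ``mean_radius``).
    """

    center: tuple[float, float] = (256.0, 160.0)
    mean_radius: float = 12.0
    boundary_irregularity: float = 0.25
    delta_hu: float = -6.0
    smooth_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if self.delta_hu > 0:
            raise ValueError("delta_hu must be <= 0 (ischemia lowers attenuation)")
        if not (0 <= self.boundary_irregularity < 1):
            raise ValueError("boundary_irregularity must lie in [0, 1)")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")


@dataclass(frozen=True)
class SubjectSlice:
    """One slice of a synthetic subject: image, candidate ROI, brain mask."""

    image: ImageSlice
    roi: ROIMask
    brain: ROIMask


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str  # "lesion" | "normal"
    slices: tuple[SubjectSlice, ...]
    true_midline: tuple[float, float]  # (offset px, angle deg) of the symmetry axis

    def __post_init__(self) -> None:
        if self.group not in ("lesion", "normal"):
            raise ValueError(f"unknown group {self.group!r}")
        n = len(self.slices)
        if self.group == "lesion" and n != 1:
            raise ValueError("lesion subjects carry exactly one slice")
        if self.group == "normal" and n != 3:
            raise ValueError("normal subjects carry exactly three slices")
        for s in self.slices:
            s.roi.require_nonempty()
            if (s.roi.mask & ~s.brain.mask).any():
                raise ValueError("candidate ROI leaves the brain")


# ---------------------------------------------------------------------------
# head slice


def _ellipse(shape, center, semi_r, semi_c, tilt_deg: float = 0.0):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    if tilt_deg:
        a = np.deg2rad(tilt_deg)
        rr, cc = np.cos(a) * rr - np.sin(a) * cc, np.sin(a) * rr + np.cos(a) * cc
    return (rr / semi_r) ** 2 + (cc / semi_c) ** 2 <= 1.0


def generate_head_slice(spec: PhantomSpec, seed: int | None = None) -> tuple[ImageSlice, ROIMask]:
    """Generate one axial head slice and its brain mask.

    The noise-free anatomy is built mirror-symmetric about the central column
    axis by explicit symmetrization, so with ``noise_sd = 0`` and
    ``asymmetry_jitter = 0`` the returned grid satisfies
    ``values == values[:, ::-1]`` exactly.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    h, w = (int(spec.image_shape[0]), int(spec.image_shape[1]))
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    skull_r, skull_c = 0.42 * h, 0.36 * w
    skull_thick = max(0.012 * min(h, w), 3.0)
    outer = _ellipse((h, w), center, skull_r, skull_c)
    brain = _ellipse((h, w), center, skull_r - skull_thick, skull_c - skull_thick)

    base = np.full((h, w), spec.mean_background)
    base[outer] = spec.mean_skull
    base[brain] = spec.mean_white

    # cortical gray-matter ribbon just inside the brain boundary
    inner = _ellipse((h, w), center, (skull_r - skull_thick) * 0.82, (skull_c - skull_thick) * 0.82)
    base[brain & ~inner] = spec.mean_gray

    # mirrored deep gray nuclei (thalamus-like), one per hemisphere
    nuc_dr, nuc_dc = 0.06 * h, 0.10 * w
    for sign in (-1.0, 1.0):
        nuc = _ellipse((h, w), (center[0] + nuc_dr, center[1] + sign * nuc_dc), 0.055 * h, 0.045 * w)
        base[nuc & brain] = spec.mean_gray

    # mirrored lateral ventricles: angled CSF slots anchoring head orientation
    for sign in (-1.0, 1.0):
        vent = _ellipse(
            (h, w),
            (center[0] - 0.055 * h, center[1] + sign * 0.055 * w),
            0.10 * h,
            0.022 * w,
            tilt_deg=sign * 14.0,
        )
        base[vent & brain] = spec.mean_csf

    base = ndimage.gaussian_filter(base, 1.0)
    base = 0.5 * (base + base[:, ::-1])  # exact mirror symmetry

    values = base
    if spec.asymmetry_jitter > 0:
        d = rng.normal(0.0, spec.asymmetry_jitter)
        half = np.arange(w)[None, :] < w / 2.0
        jit = np.where(half, d / 2.0, -d / 2.0)
        values = values + jit * brain
    if spec.noise_sd > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.noise_corr_len)
        noise *= spec.noise_sd / noise.std()
        values = values + noise

    return (
        ImageSlice(values, spacing=spec.pixel_spacing),
        ROIMask(brain),
    )


# ---------------------------------------------------------------------------
# lesions


def sample_lesion_roi(brain_mask: ROIMask, lesion_spec: LesionSpec) -> ROIMask:
    """Draw a connected blob-shaped ROI confined to one hemisphere.

    The outline is a radial perturbation of a circle: r(phi) =
    R * (1 + irregularity * s(phi)) with s a random low-order Fourier series
    normalized to max |s| = 1, so the area is always within a factor of
    (1 - irr)^2 .. (1 + irr)^2 of the disk area. Fails if the blob crosses the
    central column axis (the generating midline) or exits the brain.
    """
    brain_mask.require_nonempty()
    rng = np.random.default_rng(lesion_spec.seed)
    h, w = brain_mask.shape
    r0, c0 = lesion_spec.center
    rad = lesion_spec.mean_radius
    irr = lesion_spec.boundary_irregularity

    rr = np.arange(h)[:, None] - r0
    cc = np.arange(w)[None, :] - c0
    dist = np.hypot(rr, cc)
    if irr == 0:
        mask = dist <= rad
    else:
        # random periodic radial profile from harmonics 2..5
        ks = np.arange(2, 6)
        a = rng.standard_normal(ks.size)
        b = rng.standard_normal(ks.size)
        phi = np.arctan2(rr, cc)
        s = np.zeros((h, w))
        sup = np.zeros(720)
        grid = np.linspace(-np.pi, np.pi, 720)
        for k, ak, bk in zip(ks, a, b):
            s += ak * np.cos(k * phi) + bk * np.sin(k * phi)
            sup += ak * np.cos(k * grid) + bk * np.sin(k * grid)
        scale = np.abs(sup).max()
        if scale > 0:
            s /= scale
        mask = dist <= rad * (1.0 + irr * np.clip(s, -1.0, 1.0))
        # keep the blob connected: retain the component containing the center
        lab, n = ndimage.label(mask)
        if n > 1:
            mask = lab == lab[int(round(r0)), int(round(c0))]

    if not mask.any():
        raise ValueError("sampled lesion mask is empty")
    mid = (w - 1) / 2.0
    cols = np.nonzero(mask)[1]
    if (cols < mid).any() and (cols > mid).any():
        raise ValueError("lesion blob crosses the brain midline")
    if (mask & ~brain_mask.mask).any():
        raise ValueError("lesion blob exits the brain")
    return ROIMask(mask)


def inject_lesion(image: ImageSlice, roi: ROIMask, lesion_spec: LesionSpec) -> ImageSlice:
    """Apply the lesion effect inside ``roi``; pixels outside are untouched.

    The attenuation shift uses a feathered weight restricted to the ROI and
    normalized to mean 1 inside it, so the mean shift over the ROI equals
    ``delta_hu`` exactly (no noise realization enters the weight). Texture
    loss blends each ROI pixel toward a Gaussian-smoothed copy of the slice
    with the same feather, reducing local variance without a step edge.
    """
    roi.require_nonempty()
    roi.require_aligned(image)
    m = roi.mask
    values = image.values

    feather = ndimage.gaussian_filter(m.astype(float), 1.0) * m
    w_shift = feather / feather[m].mean()

    out = values.copy()
    if lesion_spec.smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(values, lesion_spec.smooth_sigma)
        out = out + feather * (smoothed - values)
    out = out + w_shift * lesion_spec.delta_hu
    return ImageSlice(out, spacing=image.spacing)


# ---------------------------------------------------------------------------
# subject pose and cohort assembly


def apply_pose(
    arrays: list[np.ndarray],
    angle_deg: float,
    shift: tuple[float, float],
    orders: list[int],
) -> list[np.ndarray]:
    """Rotate by ``angle_deg`` about the image center then translate by
    ``shift = (d_row, d_col)``; each array is resampled at its given spline
    order (0 for masks, 1 for images). Returns new arrays of the same shape.
    """
    h, w = arrays[0].shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    t = np.asarray(shift, dtype=float)
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    # inverse map: p_in = R^-1 (p_out - c - t) + c
    inv = rot.T
    offset = c - inv @ (c + t)
    out = []
    for arr, order in zip(arrays, orders):
        cval = float(arr.min()) if order > 0 else 0.0
        warped = ndimage.affine_transform(
            arr.astype(float), inv, offset=offset, order=order, mode="constant", cval=cval
        )
        out.append(warped > 0.5 if order == 0 else warped)
    return out


def pose_midline(angle_deg: float, shift: tuple[float, float]) -> tuple[float, float]:
    """(offset, angle) of the symmetry axis after :func:`apply_pose`.

    The vertical axis through the center maps to the line through
    ``center + shift`` with direction ``R(angle) @ (1, 0)``; its signed column
    offset where it crosses the central row is ``d_col - d_row * tan(angle)``.
    """
    dr, dc = shift
    return (dc - dr * np.tan(np.deg2rad(angle_deg)), angle_deg)


def _valid_centers(brain: np.ndarray, margin: float) -> np.ndarray:
    """Boolean grid of centers at distance > margin from the brain boundary
    and > margin from the midline column axis."""
    dist = ndimage.distance_transform_edt(brain)
    w = brain.shape[1]
    mid = (w - 1) / 2.0
    coldist = np.abs(np.arange(w)[None, :] - mid)
    return (dist > margin) & (coldist > margin)


def _sample_lesion_spec(rng: np.random.Generator, base: LesionSpec) -> LesionSpec:
    """Draw per-subject lesion morphology; the effect size stays at ``base``'s."""
    return replace(
        base,
        mean_radius=float(rng.uniform(9.0, 18.0)),
        boundary_irregularity=float(rng.uniform(0.1, 0.35)),
        seed=int(rng.integers(2**31 - 1)),
    )


def generate_cohort(
    n_lesion: int,
    n_normal: int,
    spec: PhantomSpec | None = None,
    lesion_spec: LesionSpec | None = None,
    seed: int = 0,
    pose_angle_max: float = 5.0,
    pose_shift_max: float = 8.0,
    max_placement_tries: int = 50,
) -> list[SyntheticSubject]:
    """Generate a full synthetic cohort.

    ``n_lesion`` subjects contribute one slice each with an injected lesion;
    ``n_normal`` subjects contribute three slices each whose ROIs are
    lesion-shaped masks drawn from the lesion subjects' mask library and
    placed at a valid position inside the control brain. Every subject gets a
    small random in-plane pose (rotation, shift) recorded in
    ``true_midline``. Deterministic per ``seed``.
    """
    if n_lesion < 1 or n_normal < 1:
        raise ValueError("cohort needs at least one subject per group")
    spec = spec if spec is not None else PhantomSpec()
    base_lesion = lesion_spec if lesion_spec is not None else LesionSpec()
    root = np.random.SeedSequence(seed)
    lesion_ss, normal_ss = root.spawn(2)
    subjects: list[SyntheticSubject] = []
    mask_library: list[np.ndarray] = []

    for i, child in enumerate(lesion_ss.spawn(n_lesion)):
        rng = np.random.default_rng(child)
        img, brain = generate_head_slice(spec, seed=int(rng.integers(2**31 - 1)))
        lspec = _sample_lesion_spec(rng, base_lesion)
        centers = _valid_centers(brain.mask, lspec.mean_radius * (1 + lspec.boundary_irregularity) + 3)
        idx = np.flatnonzero(centers.ravel())
        if idx.size == 0:
            raise RuntimeError("no valid lesion centers in the brain")
        pick = idx[rng.integers(idx.size)]
        lspec = replace(lspec, center=(float(pick // centers.shape[1]), float(pick % centers.shape[1])))
        roi = sample_lesion_roi(brain, lspec)
        img = inject_lesion(img, roi, lspec)
        mask_library.append(roi.mask)

        angle = float(rng.uniform(-pose_angle_max, pose_angle_max))
        shift = (float(rng.uniform(-pose_shift_max, pose_shift_max)),
                 float(rng.uniform(-pose_shift_max, pose_shift_max)))
        vals, rmask, bmask = apply_pose(
            [img.values, roi.mask, brain.mask], angle, shift, orders=[1, 0, 0]
        )
        rmask &= bmask
        subjects.append(
            SyntheticSubject(
                subject_id=f"lesion_{i:03d}",
                group="lesion",
                slices=(SubjectSlice(ImageSlice(vals, img.spacing), ROIMask(rmask), ROIMask(bmask)),),
                true_midline=pose_midline(angle, shift),
            )
        )

    for i, child in enumerate(normal_ss.spawn(n_normal)):
        rng = np.random.default_rng(child)
        angle = float(rng.uniform(-pose_angle_max, pose_angle_max))
        shift = (float(rng.uniform(-pose_shift_max, pose_shift_max)),
                 float(rng.uniform(-pose_shift_max, pose_shift_max)))
        recs = []
        for _ in range(3):
            img, brain = generate_head_slice(spec, seed=int(rng.integers(2**31 - 1)))
            mask = _place_library_mask(rng, mask_library, brain.mask, max_placement_tries)
            vals, rmask, bmask = apply_pose(
                [img.values, mask, brain.mask], angle, shift, orders=[1, 0, 0]
            )
            rmask &= bmask
            recs.append(SubjectSlice(ImageSlice(vals, img.spacing), ROIMask(rmask), ROIMask(bmask)))
        subjects.append(
            SyntheticSubject(
                subject_id=f"normal_{i:03d}",
                group="normal",
                slices=tuple(recs),
                true_midline=pose_midline(angle, shift),
            )
        )
    return subjects


def _place_library_mask(
    rng: np.random.Generator,
    library: list[np.ndarray],
    brain: np.ndarray,
    max_tries: int,
) -> np.ndarray:
    """Translate a randomly chosen library mask to a valid in-brain position."""
    for _ in range(max_tries):
        proto = library[rng.integers(len(library))]
        rows, cols = np.nonzero(proto)
        cr, cc = rows.mean(), cols.mean()
        half = max(rows.max() - rows.min(), cols.max() - cols.min()) / 2.0
        centers = _valid_centers(brain, half + 3)
        idx = np.flatnonzero(centers.ravel())
        if idx.size == 0:
            continue
        pick = idx[rng.integers(idx.size)]
        tr = pick // centers.shape[1] - cr
        tc = pick % centers.shape[1] - cc
        new = np.zeros_like(proto)
        nr = np.round(rows + tr).astype(int)
        nc = np.round(cols + tc).astype(int)
        if (nr < 0).any() or (nc < 0).any() or (nr >= brain.shape[0]).any() or (nc >= brain.shape[1]).any():
            continue
        new[nr, nc] = True
        if (new & ~brain).any():
            continue
        mid = (brain.shape[1] - 1) / 2.0
        if (nc < mid).any() and (nc > mid).any():
            continue
        return new
    raise RuntimeError("could not place a projected ROI inside the control brain")
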