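"""Two-stage 2D alignment: coarse rotation search, then affine refinement.

The lesion ground truth is drawn on a "moving" slice (in the clinical
workflow, a diffusion-weighted MR slice) and must be projected onto the
"fixed" CT slice. Stage one scans a rotation grid (the in-plane analog of
multiplanar reformatting to a consistent angle); stage two refines
translation, rotation and anisotropic scale by derivative-free local
optimization of normalized mutual information (NMI), the standard similarity
for cross-modality alignment.

Affine convention: parameters act about the image center in the fixed order
scale -> rotate -> translate; row-major pixel coordinates, 0-based.
``tx`` shifts columns (x), ``ty`` shifts rows (y); ``theta`` is in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .image import ImageSlice, ROIMask

log = logging.getLogger(__name__)

__all__ = [
    "AffineParams",
    "RegistrationResult",
    "normalized_mutual_information",
    "warp_by_matrix",
    "warp_image",
    "coarse_register",
    "fine_register",
    "register",
    "transform_mask",
]


@dataclass(frozen=True)
class AffineParams:
    tx: float = 0.0  # column shift, px
    ty: float = 0.0  # row shift, px
    theta: float = 0.0  # degrees
    sx: float = 1.0
    sy: float = 1.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 forward matrix in (row, col, 1) coordinates about the center."""
        c = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        a = np.deg2rad(self.theta)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        scale = np.diag([self.sy, self.sx])  # row scale = sy, col scale = sx
        lin = rot @ scale
        t = np.array([self.ty, self.tx])
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = c + t - lin @ c
        return m

    @staticmethod
    def from_matrix(m: np.ndarray, shape: tuple[int, int]) -> "AffineParams":
        """Decompose a shear-free forward matrix back into parameters."""
        lin = m[:2, :2]
        sy = float(np.hypot(lin[0, 0], lin[1, 0]))
        theta = float(np.rad2deg(np.arctan2(lin[1, 0], lin[0, 0])))
        det = float(np.linalg.det(lin))
        sx = det / sy
        c = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        t = m[:2, 2] + lin @ c - c
        return AffineParams(tx=float(t[1]), ty=float(t[0]), theta=theta, sx=sx, sy=sy)


@dataclass(frozen=True)
class RegistrationResult:
    params: AffineParams
    metric: float
    converged: bool


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Studholme NMI, (H(A) + H(B)) / H(A, B); 1 for independent images."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    hxy = -np.sum(pxy[pxy > 0] * np.log(pxy[pxy > 0]))
    if hxy == 0:
        return 2.0  # both images constant: perfectly (trivially) aligned
    return float((hx + hy) / hxy)


def warp_by_matrix(
    image: np.ndarray, matrix: np.ndarray, order: int = 1, cval: float | None = None
) -> np.ndarray:
    """Resample ``image`` at ``matrix @ (row, col, 1)`` (output-to-input map)."""
    if cval is None:
        cval = float(image.min())
    return ndimage.affine_transform(
        image.astype(float), matrix[:2, :2], offset=matrix[:2, 2],
        order=order, mode="constant", cval=cval,
    )


def warp_image(
    image: np.ndarray, params: AffineParams, order: int = 1, cval: float | None = None
) -> np.ndarray:
    """Apply the forward affine to image content (inverse-map resampling)."""
    m = params.matrix(image.shape)
    return warp_by_matrix(image, np.linalg.inv(m), order=order, cval=cval)


def coarse_register(
    fixed: ImageSlice, moving: ImageSlice, angle_grid: np.ndarray | None = None, bins: int = 64
) -> float:
    """Grid search for the rotation maximizing NMI(fixed, rotate(moving)).

    Ties are broken toward the smallest |angle| (candidates are visited in
    order of increasing |angle| and only a strictly better metric wins), so
    featureless images return 0 when the grid contains it.
    """
    if angle_grid is None:
        angle_grid = np.arange(-15.0, 15.0 + 0.5, 1.0)
    angle_grid = np.asarray(angle_grid, dtype=float)
    if angle_grid.size == 0:
        raise ValueError("empty angle grid")
    order = np.lexsort((angle_grid, np.abs(angle_grid)))
    best_angle, best_metric = None, -np.inf
    for ang in angle_grid[order]:
        rotated = warp_image(moving.values, AffineParams(theta=float(ang)))
        m = normalized_mutual_information(fixed.values, rotated, bins=bins)
        if m > best_metric + 1e-12:
            best_metric, best_angle = m, float(ang)
    return best_angle


# optimization scales: 1 unit of the optimizer's space per parameter
_PARAM_SCALE = np.array([10.0, 10.0, 5.0, 0.05, 0.05])  # tx, ty, theta, sx-1, sy-1


def _nmi_against(fixed_values: np.ndarray, bins: int):
    """Precompute the fixed image's bin indices for fast repeated NMI."""
    fv = fixed_values
    lo, hi = float(fv.min()), float(fv.max())
    if hi == lo:
        return lambda b: 2.0
    fidx = np.clip(((fv - lo) / (hi - lo) * bins).astype(np.int32), 0, bins - 1).ravel()

    def score(b: np.ndarray) -> float:
        blo, bhi = float(b.min()), float(b.max())
        if bhi == blo:
            return 2.0
        bidx = np.clip(((b - blo) / (bhi - blo) * bins).astype(np.int32), 0, bins - 1).ravel()
        joint = np.bincount(fidx * bins + bidx, minlength=bins * bins).astype(float)
        pxy = joint / joint.sum()
        pxy = pxy.reshape(bins, bins)
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
        hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
        hxy = -np.sum(pxy[pxy > 0] * np.log(pxy[pxy > 0]))
        return float((hx + hy) / hxy) if hxy > 0 else 2.0

    return score


def fine_register(
    fixed: ImageSlice,
    moving: ImageSlice,
    init: AffineParams | None = None,
    bins: int = 64,
    maxiter: int = 500,
    tol: float = 1e-3,
    smooth_sigma: float = 0.0,
) -> RegistrationResult:
    """Refine (tx, ty, theta, sx, sy) by derivative-free NMI maximization.

    Powell's method from ``init``; the returned parameters never score below
    the initialization (falls back to ``init`` otherwise). Non-convergence
    within the iteration cap returns the best point found with
    ``converged=False`` and a logged warning. ``smooth_sigma > 0`` evaluates
    the metric on Gaussian-smoothed copies of both images, which regularizes
    the otherwise comb-like NMI landscape of sharp-edged images.
    """
    init = init if init is not None else AffineParams()
    x0 = np.array([init.tx, init.ty, init.theta, init.sx - 1.0, init.sy - 1.0]) / _PARAM_SCALE
    fixed_v, moving_v = fixed.values, moving.values
    if smooth_sigma > 0:
        fixed_v = ndimage.gaussian_filter(fixed_v, smooth_sigma)
        moving_v = ndimage.gaussian_filter(moving_v, smooth_sigma)
    score = _nmi_against(fixed_v, bins)

    def unpack(x: np.ndarray) -> AffineParams:
        tx, ty, theta, dsx, dsy = x * _PARAM_SCALE
        return AffineParams(tx=tx, ty=ty, theta=theta, sx=max(1e-3, 1 + dsx), sy=max(1e-3, 1 + dsy))

    def objective(x: np.ndarray) -> float:
        return -score(warp_image(moving_v, unpack(x)))

    res = optimize.minimize(
        objective,
        x0,
        method="Powell",
        options={"maxiter": maxiter, "xtol": tol, "ftol": tol * 1e-3},
    )
    converged = bool(res.success)
    if not converged:
        log.warning("fine registration did not converge within %d iterations", maxiter)
    init_metric = -objective(x0)
    final_metric = -float(res.fun)
    if final_metric < init_metric:
        return RegistrationResult(init, init_metric, converged)
    return RegistrationResult(unpack(res.x), final_metric, converged)


def _fft_translation(f_centered_fft, g: np.ndarray, shape) -> tuple[float, float]:
    """Integer (d_row, d_col) maximizing the circular cross-correlation."""
    h, w = shape
    xc = np.fft.irfft2(f_centered_fft * np.conj(np.fft.rfft2(g - g.mean())), s=(h, w))
    idx = np.unravel_index(int(np.argmax(xc)), xc.shape)
    dr = idx[0] if idx[0] <= h // 2 else idx[0] - h
    dc = idx[1] if idx[1] <= w // 2 else idx[1] - w
    return float(dr), float(dc)


def _head_mask(values: np.ndarray, threshold: float) -> np.ndarray:
    return values > threshold


def _informed_init(
    fixed: ImageSlice, moving: ImageSlice, head_threshold: float
) -> AffineParams | None:
    """Initialization from anatomy: rotation from the difference of the two
    heads' symmetry-axis angles, scale from the ratio of head bounding-box
    extents after unrotating, translation left to the FFT stage."""
    from .midline import estimate_midline  # local import avoids a cycle

    try:
        hf = _head_mask(fixed.values, head_threshold)
        hm = _head_mask(moving.values, head_threshold)
        mlf = estimate_midline(fixed, ROIMask(hf), downsample=2)
        mlm = estimate_midline(moving, ROIMask(hm), downsample=2)
    except ValueError:
        return None
    theta0 = mlf.angle - mlm.angle

    def extents(m):
        rr, cc = np.nonzero(m)
        return rr.max() - rr.min() + 1, cc.max() - cc.min() + 1

    unrot = warp_image(moving.values, AffineParams(theta=theta0), order=0)
    er, ec = extents(_head_mask(unrot, head_threshold))
    fr, fc = extents(hf)
    return AffineParams(theta=theta0, sx=fc / ec, sy=fr / er)


def register(
    fixed: ImageSlice,
    moving: ImageSlice,
    angle_grid: np.ndarray | None = None,
    bins: int = 64,
    top_k: int = 2,
    min_angle_gap: float = 3.0,
    coarse_sigma: float = 2.0,
    fine_sigma: float = 0.5,
    head_threshold: float = -200.0,
) -> RegistrationResult:
    """Full two-stage alignment of ``moving`` onto ``fixed``.

    Several starting points are generated — an anatomy-informed one (symmetry
    -axis angle difference plus head-extent scale ratio) and the ``top_k``
    angle-distinct candidates of an FFT-translation scan over the rotation
    grid — and each is refined by a Powell chain on moderately smoothed
    images (``coarse_sigma``) then lightly smoothed images (``fine_sigma``).
    The best final metric wins. The multi-start guards against the
    mirror-symmetry alias of near-symmetric heads, where a wrong rotation
    plus a compensating shift is locally optimal.
    """
    if angle_grid is None:
        angle_grid = np.arange(-15.0, 15.0 + 0.5, 1.0)
    fx = ndimage.gaussian_filter(fixed.values, coarse_sigma)
    mv = ndimage.gaussian_filter(moving.values, coarse_sigma)
    score = _nmi_against(fx, bins)
    f_fft = np.fft.rfft2(fx - fx.mean())

    inits: list[AffineParams] = []
    informed = _informed_init(fixed, moving, head_threshold)
    if informed is not None:
        pre = warp_image(mv, informed)
        dr, dc = _fft_translation(f_fft, pre, fixed.shape)
        inits.append(
            AffineParams(tx=dc, ty=dr, theta=informed.theta, sx=informed.sx, sy=informed.sy)
        )
    candidates = []
    for ang in np.asarray(angle_grid, dtype=float):
        rotated = warp_image(mv, AffineParams(theta=float(ang)))
        dr, dc = _fft_translation(f_fft, rotated, fixed.shape)
        shifted = warp_image(rotated, AffineParams(tx=dc, ty=dr))
        candidates.append((score(shifted), float(ang), dr, dc))
    candidates.sort(key=lambda c: (-c[0], abs(c[1])))
    picked = []
    for cand in candidates:
        if all(abs(cand[1] - p[1]) >= min_angle_gap for p in picked):
            picked.append(cand)
        if len(picked) == top_k:
            break
    inits.extend(AffineParams(tx=dc, ty=dr, theta=ang) for _, ang, dr, dc in picked)

    best: RegistrationResult | None = None
    for init in inits:
        stage1 = fine_register(
            fixed, moving, init=init, bins=bins, maxiter=8, smooth_sigma=coarse_sigma
        )
        stage2 = fine_register(
            fixed, moving, init=stage1.params, bins=bins, tol=1e-4, smooth_sigma=fine_sigma
        )
        if best is None or stage2.metric > best.metric:
            best = stage2
    # final polish on the raw (unsmoothed) metric for subpixel precision;
    # fine_register falls back to its init if the raw metric would worsen
    return fine_register(fixed, moving, init=best.params, bins=bins, tol=1e-4)


def transform_mask(
    mask: ROIMask, params: AffineParams, target_shape: tuple[int, int] | None = None
) -> ROIMask:
    """Project a binary mask under the affine (nearest-neighbor resampling)."""
    mask.require_nonempty()
    shape = target_shape if target_shape is not None else mask.shape
    m = params.matrix(mask.shape)
    inv = np.linalg.inv(m)
    out = ndimage.affine_transform(
        mask.mask.astype(float), inv[:2, :2], offset=inv[:2, 2],
        output_shape=shape, order=0, mode="constant", cval=0.0,
    )
    out = out > 0.5
    if not out.any():
        raise ValueError("transformed mask left the field of view")
    return ROIMask(out)
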