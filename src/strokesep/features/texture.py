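"""Size-zone, dependence, and neighborhood-tone-difference texture classes.

* GLSZM — zones are 8-connected components of equal gray level inside the
  mask; P(i, s) counts zones of level i and size s (16 features).
* GLDM — for each mask pixel, the dependence count is the number of its
  8-neighbors inside the mask with the same gray level (tolerance 0);
  P(i, d) counts pixels of level i with dependence d (14 features).
* NGTDM — s_i accumulates |i - A| over mask pixels of level i, where A is
  the mean level of the pixel's in-mask 8-neighbors (5 features).

These are orientation-free, so no angle averaging applies.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "auxiliary_texture_features",
]

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_EIGHT = np.ones((3, 3), dtype=bool)
_NEIGHBOR_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    ng = int(levels[mask].max())
    zones: list[tuple[int, int]] = []
    for lv in range(1, ng + 1):
        lab, n = ndimage.label((levels == lv) & mask, structure=_EIGHT)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((lv, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    p = np.zeros((ng, max_size))
    for lv, s in zones:
        p[lv - 1, s - 1] += 1
    return p


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI")
    p = glszm_matrix(levels, mask)
    nz_total = p.sum()
    i = np.arange(1, p.shape[0] + 1)[:, None].astype(float)
    s = np.arange(1, p.shape[1] + 1)[None, :].astype(float)
    pi = p.sum(axis=1)
    ps = p.sum(axis=0)
    pr = p / nz_total
    mu_i = float(np.sum(i * pr))
    mu_s = float(np.sum(s * pr))
    nz = pr > 0
    return {
        "SmallAreaEmphasis": float(np.sum(p / s**2) / nz_total),
        "LargeAreaEmphasis": float(np.sum(p * s**2) / nz_total),
        "GrayLevelNonUniformity": float(np.sum(pi**2) / nz_total),
        "GrayLevelNonUniformityNormalized": float(np.sum(pi**2) / nz_total**2),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz_total),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz_total**2),
        "ZonePercentage": float(nz_total / n_pixels),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pr)),
        "ZoneVariance": float(np.sum((s - mu_s) ** 2 * pr)),
        "ZoneEntropy": float(-np.sum(pr[nz] * np.log2(pr[nz]))),
        "LowGrayLevelZoneEmphasis": float(np.sum(p / i**2) / nz_total),
        "HighGrayLevelZoneEmphasis": float(np.sum(p * i**2) / nz_total),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(p / (i**2 * s**2)) / nz_total),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(p * i**2 / s**2) / nz_total),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(p * s**2 / i**2) / nz_total),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(p * i**2 * s**2) / nz_total),
    }


def _dependence_counts(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel count of in-mask 8-neighbors with an identical gray level."""
    h, w = levels.shape
    dep = np.zeros((h, w), dtype=int)
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        same = (
            (levels[r0s:r0e, c0s:c0e] == levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc])
            & mask[r0s:r0e, c0s:c0e]
            & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        )
        dep[r0s:r0e, c0s:c0e] += same
    return dep


def gldm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    nv = int(mask.sum())
    if nv == 0:
        raise ValueError("empty ROI")
    ng = int(levels[mask].max())
    dep = _dependence_counts(levels, mask)
    p = np.zeros((ng, 9))  # dependence counts 0..8 stored at column d
    np.add.at(p, (levels[mask] - 1, dep[mask]), 1.0)
    used = np.nonzero(p.sum(axis=0))[0]
    p = p[:, : used.max() + 1]
    i = np.arange(1, ng + 1)[:, None].astype(float)
    d = np.arange(1, p.shape[1] + 1)[None, :].astype(float)  # dependence d = count + 1
    pi = p.sum(axis=1)
    pd = p.sum(axis=0)
    pr = p / nv
    mu_i = float(np.sum(i * pr))
    mu_d = float(np.sum(d * pr))
    nz = pr > 0
    return {
        "SmallDependenceEmphasis": float(np.sum(p / d**2) / nv),
        "LargeDependenceEmphasis": float(np.sum(p * d**2) / nv),
        "GrayLevelNonUniformity": float(np.sum(pi**2) / nv),
        "DependenceNonUniformity": float(np.sum(pd**2) / nv),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nv**2),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pr)),
        "DependenceVariance": float(np.sum((d - mu_d) ** 2 * pr)),
        "DependenceEntropy": float(-np.sum(pr[nz] * np.log2(pr[nz]))),
        "LowGrayLevelEmphasis": float(np.sum(p / i**2) / nv),
        "HighGrayLevelEmphasis": float(np.sum(p * i**2) / nv),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (i**2 * d**2)) / nv),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * i**2 / d**2) / nv),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * d**2 / i**2) / nv),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * i**2 * d**2) / nv),
    }


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    nv = int(mask.sum())
    if nv == 0:
        raise ValueError("empty ROI")
    ng = int(levels[mask].max())
    h, w = levels.shape
    nb_sum = np.zeros((h, w))
    nb_cnt = np.zeros((h, w))
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        inmask = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        nb_sum[r0s:r0e, c0s:c0e] += levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc] * inmask
        nb_cnt[r0s:r0e, c0s:c0e] += inmask

    s = np.zeros(ng)
    n = np.zeros(ng)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        lv = levels[r, c]
        n[lv - 1] += 1
        if nb_cnt[r, c] > 0:
            s[lv - 1] += abs(lv - nb_sum[r, c] / nb_cnt[r, c])

    p = n / nv
    i = np.arange(1, ng + 1).astype(float)
    present = p > 0
    ngp = int(present.sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pij_valid = np.outer(present, present)

    sum_ps = float(np.sum(p * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            float(np.sum(np.outer(p, p)[pij_valid] * ((ii - jj) ** 2)[pij_valid]))
            / (ngp * (ngp - 1))
            * float(s.sum())
            / nv
        )
    else:
        contrast = 0.0
    denom_busy = float(np.sum(np.abs((ii * p[:, None]) - (jj * p[None, :]))[pij_valid]))
    busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        comp_term = np.abs(ii - jj) * (
            (p[:, None] * s[:, None] + p[None, :] * s[None, :])
            / (p[:, None] + p[None, :])
        )
    complexity = float(np.nansum(np.where(pij_valid, comp_term, 0.0))) / nv
    s_sum = float(s.sum())
    if s_sum > 0:
        strength = float(np.sum(((p[:, None] + p[None, :]) * (ii - jj) ** 2)[pij_valid])) / s_sum
    else:
        strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


def auxiliary_texture_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """GLSZM + GLDM + NGTDM features with class-prefixed names."""
    out = {}
    out.update({f"glszm_{k}": v for k, v in glszm_features(levels, mask).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_features(levels, mask).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(levels, mask).items()})
    return out
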