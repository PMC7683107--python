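"""Gray-level run-length matrix (GLRLM) features.

A run is a maximal straight segment of mask pixels sharing one gray level
along a direction; pixels outside the mask break runs. The matrix P(i, j)
counts runs of level i and length j per direction; the 16 standard features
are computed per direction and averaged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GLRLM_NAMES", "glrlm_matrix", "glrlm_features"]

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _lines(levels: np.ndarray, mask: np.ndarray, angle: int):
    """Yield (level_seq, mask_seq) 1D lines along the given direction."""
    if angle == 0:  # horizontal
        for r in range(levels.shape[0]):
            yield levels[r], mask[r]
    elif angle == 90:  # vertical
        for c in range(levels.shape[1]):
            yield levels[:, c], mask[:, c]
    elif angle == 135:  # main diagonals (dr=1, dc=1)
        h, w = levels.shape
        for off in range(-h + 1, w):
            yield levels.diagonal(off), mask.diagonal(off)
    elif angle == 45:  # anti-diagonals (dr=-1, dc=1)
        lv = levels[:, ::-1]
        mk = mask[:, ::-1]
        h, w = lv.shape
        for off in range(-h + 1, w):
            yield lv.diagonal(off), mk.diagonal(off)
    else:
        raise ValueError(f"unsupported run angle {angle}")


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, angle: int) -> np.ndarray:
    """Run-length matrix P[i-1, j-1] for one direction (levels i, lengths j)."""
    mask = np.asarray(mask, dtype=bool)
    ng = int(levels[mask].max())
    max_len = max(levels.shape)
    p = np.zeros((ng, max_len))
    for lv, mk in _lines(levels, mask, angle):
        n = len(lv)
        start = 0
        while start < n:
            if not mk[start]:
                start += 1
                continue
            end = start + 1
            while end < n and mk[end] and lv[end] == lv[start]:
                end += 1
            p[lv[start] - 1, end - start - 1] += 1
            start = end
    # trim unused long-run columns
    used = np.nonzero(p.sum(axis=0))[0]
    return p[:, : used.max() + 1] if used.size else p[:, :1]


def _features_one_matrix(p: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = p.sum()
    i = np.arange(1, p.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, p.shape[1] + 1)[None, :].astype(float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    pr = p / nr
    mu_i = float(np.sum(i * pr))
    mu_j = float(np.sum(j * pr))
    nz = pr > 0
    return {
        "ShortRunEmphasis": float(np.sum(p / j**2) / nr),
        "LongRunEmphasis": float(np.sum(p * j**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(pi**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pi**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(pj**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pj**2) / nr**2),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pr)),
        "RunVariance": float(np.sum((j - mu_j) ** 2 * pr)),
        "RunEntropy": float(-np.sum(pr[nz] * np.log2(pr[nz]))),
        "LowGrayLevelRunEmphasis": float(np.sum(p / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(p * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(p / (i**2 * j**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(p * i**2 / j**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(p * j**2 / i**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(p * i**2 * j**2) / nr),
    }


def glrlm_features(
    levels: np.ndarray, mask: np.ndarray, angles: tuple[int, ...] = (0, 45, 90, 135)
) -> dict[str, float]:
    """The 16 GLRLM features averaged over run directions."""
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI")
    per_angle = [_features_one_matrix(glrlm_matrix(levels, mask, a), n_pixels) for a in angles]
    return {name: float(np.mean([f[name] for f in per_angle])) for name in GLRLM_NAMES}
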