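"""Gray-level co-occurrence matrix (GLCM) features.

For each angle (0, 45, 90, 135 degrees) and pixel distance, pairs of in-mask
gray levels at the given offset are accumulated, the matrix is symmetrized
and normalized to sum 1, the 24 standard features are computed per angle, and
the per-angle values are averaged. Degenerate single-level ROIs give
Contrast 0 and Correlation 1 by convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GLCM_NAMES", "glcm_matrix", "glcm_features", "ANGLE_OFFSETS"]

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "JointAverage",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

# (d_row, d_col) offsets; angles measured as in standard 2D texture analysis
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, distance: int, angle: int
) -> np.ndarray:
    """Symmetric, normalized Ng x Ng co-occurrence matrix for one offset.

    Returns the zero matrix if no valid pixel pair exists at this offset.
    """
    mask = np.asarray(mask, dtype=bool)
    ng = int(levels[mask].max()) if mask.any() else 0
    if ng == 0:
        raise ValueError("empty ROI")
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = levels.shape
    p = np.zeros((ng, ng))
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = levels[r0s:r0e, c0s:c0e]
    b = levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    ma = mask[r0s:r0e, c0s:c0e]
    mb = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = ma & mb
    if valid.any():
        i = a[valid] - 1
        j = b[valid] - 1
        np.add.at(p, (i, j), 1.0)
        p = p + p.T  # symmetrize
        p /= p.sum()
    return p


_EPS = np.finfo(float).eps


def _features_one_matrix(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    if p.sum() == 0:
        # no valid pairs at this offset: treat as degenerate
        p = np.zeros((1, 1))
        p[0, 0] = 1.0
        ng = 1
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float(np.sum(px * i))
    sigma_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))

    # difference |i-j| and sum i+j marginals
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pxpy = px[:, None] * px[None, :]
    valid = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[valid] * np.log2(pxpy[valid])))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))

    da = float(np.sum(k_diff * p_diff))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if sigma_x > 0:
        correlation = float((np.sum(ii * jj * p) - mu_x**2) / sigma_x**2)
    else:
        correlation = 1.0

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2.0)) if off.any() else 0.0

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px_i px_k)
    if ng > 1 and (px > 0).all():
        q = np.zeros((ng, ng))
        for k in range(ng):
            q += np.outer(p[:, k] / px, p[:, k] / px[k])
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    sp = p_sum[p_sum > 0]
    dp = p_diff[p_diff > 0]
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu_x) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu_x) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu_x) ** 2 * p)),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(dp * np.log2(dp))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "JointAverage": mu_x,
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(sp * np.log2(sp))),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
        "MCC": mcc,
    }


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    distances: tuple[int, ...] = (1,),
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> dict[str, float]:
    """The 24 GLCM features, averaged over all (distance, angle) offsets."""
    per_offset = []
    for d in distances:
        for ang in angles:
            p = glcm_matrix(levels, mask, d, ang)
            per_offset.append(_features_one_matrix(p))
    return {name: float(np.mean([f[name] for f in per_offset])) for name in GLCM_NAMES}
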