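"""Independent brute-force oracles for feature and information-gain tests.

Everything here is written with explicit Python loops and dictionaries,
deliberately avoiding the vectorized code paths of the package, so agreement
between the two is a meaningful check of both.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict

import numpy as np

LOG2 = math.log(2.0)


def _log2(x: float) -> float:
    return math.log(x) / LOG2


# ---------------------------------------------------------------------------
# first order


def first_order_oracle(values, mask, levels) -> dict[str, float]:
    """18 first-order features from sorted-list arithmetic."""
    v = sorted(float(x) for x, m in zip(np.asarray(values).ravel(), np.asarray(mask).ravel()) if m)
    n = len(v)
    mean = sum(v) / n

    def percentile(q: float) -> float:
        # linear interpolation between closest ranks (numpy 'linear' method)
        pos = (n - 1) * q / 100.0
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    p10, p25, p50, p75, p90 = (percentile(q) for q in (10, 25, 50, 75, 90))
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    lv_counts = Counter(int(l) for l, m in zip(np.asarray(levels).ravel(), np.asarray(mask).ravel()) if m)
    probs = [c / n for c in lv_counts.values()]
    return {
        "Energy": sum(x**2 for x in v),
        "TotalEnergy": sum(x**2 for x in v),  # caller rescales by pixel area
        "Entropy": -sum(p * _log2(p) for p in probs if p > 0),
        "Minimum": v[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": v[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": v[-1] - v[0],
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation": (
            sum(abs(x - rmean) for x in robust) / len(robust) if robust else 0.0
        ),
        "RootMeanSquared": math.sqrt(sum(x**2 for x in v) / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p**2 for p in probs),
    }


# ---------------------------------------------------------------------------
# GLCM

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix_oracle(levels, mask, distance, angle):
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    ng = max(int(levels[r][c]) for r, c in zip(*np.nonzero(mask)))
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    p = [[0.0] * ng for _ in range(ng)]
    h, w = levels.shape
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = int(levels[r, c]) - 1, int(levels[r2, c2]) - 1
                p[i][j] += 1
                p[j][i] += 1  # symmetric
                total += 2
    if total:
        p = [[x / total for x in row] for row in p]
    return np.array(p)


def glcm_features_oracle(levels, mask, distances=(1,), angles=(0, 45, 90, 135)):
    results = []
    for d in distances:
        for ang in angles:
            p = glcm_matrix_oracle(levels, mask, d, ang)
            results.append(_glcm_one(p))
    return {k: float(np.mean([r[k] for r in results])) for k in results[0]}


def _glcm_one(p):
    ng = p.shape[0]
    if p.sum() == 0:
        p = np.array([[1.0]])
        ng = 1
    px = [sum(p[i]) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum(px[i] * (i + 1 - mu) ** 2 for i in range(ng))
    p_diff = defaultdict(float)
    p_sum = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j + 2] += p[i][j]
    da = sum(k * v for k, v in p_diff.items())
    hxy = -sum(p[i][j] * _log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hxy1 = -sum(
        p[i][j] * _log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * px[j] > 0
    )
    hx = -sum(q * _log2(q) for q in px if q > 0)
    if ng > 1 and all(q > 0 for q in px):
        q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                q[i][j] = sum(p[i][k] * p[j][k] / (px[i] * px[k]) for k in range(ng))
        ev = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, ev[-2]))
    else:
        mcc = 1.0
    out = {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterProminence": sum(
            (i + j + 2 - 2 * mu) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            (i + j + 2 - 2 * mu) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            (i + j + 2 - 2 * mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": (
            (
                sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)) - mu * mu
            )
            / sigma2
            if sigma2 > 0
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in p_diff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "JointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Idmn": sum(p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)),
        "Id": sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Idn": sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "JointAverage": mu,
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * _log2(v) for v in p_sum.values() if v > 0),
        "SumSquares": sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "MCC": mcc,
    }
    return out


# ---------------------------------------------------------------------------
# GLRLM


def runs_oracle(levels, mask, angle):
    """All (level, length) maximal runs along one direction, by walking rays."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    dr, dc = _OFFSETS[angle]
    runs = []
    # starting points: cells with no in-bounds predecessor along (dr, dc)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue
            seq = []
            rr, cc = r, c
            while 0 <= rr < h and 0 <= cc < w:
                seq.append((int(levels[rr, cc]), bool(mask[rr, cc])))
                rr += dr
                cc += dc
            k = 0
            while k < len(seq):
                lv, inm = seq[k]
                if not inm:
                    k += 1
                    continue
                length = 1
                while k + length < len(seq) and seq[k + length][1] and seq[k + length][0] == lv:
                    length += 1
                runs.append((lv, length))
                k += length
    return runs


def glrlm_features_oracle(levels, mask, angles=(0, 45, 90, 135)):
    n_pix = int(np.asarray(mask, bool).sum())
    per_angle = []
    for ang in angles:
        runs = runs_oracle(levels, mask, ang)
        per_angle.append(_rl_features(runs, n_pix))
    return {k: float(np.mean([r[k] for r in per_angle])) for k in per_angle[0]}


def _rl_features(runs, n_pix):
    nr = len(runs)
    cnt = Counter(runs)
    pi = Counter(lv for lv, _ in runs)
    pj = Counter(ln for _, ln in runs)
    mu_i = sum(lv * c for lv, c in pi.items()) / nr
    mu_j = sum(ln * c for ln, c in pj.items()) / nr
    return {
        "ShortRunEmphasis": sum(c / ln**2 for (_, ln), c in cnt.items()) / nr,
        "LongRunEmphasis": sum(c * ln**2 for (_, ln), c in cnt.items()) / nr,
        "GrayLevelNonUniformity": sum(c**2 for c in pi.values()) / nr,
        "GrayLevelNonUniformityNormalized": sum(c**2 for c in pi.values()) / nr**2,
        "RunLengthNonUniformity": sum(c**2 for c in pj.values()) / nr,
        "RunLengthNonUniformityNormalized": sum(c**2 for c in pj.values()) / nr**2,
        "RunPercentage": nr / n_pix,
        "GrayLevelVariance": sum((lv - mu_i) ** 2 * c for lv, c in pi.items()) / nr,
        "RunVariance": sum((ln - mu_j) ** 2 * c for ln, c in pj.items()) / nr,
        "RunEntropy": -sum((c / nr) * _log2(c / nr) for c in cnt.values()),
        "LowGrayLevelRunEmphasis": sum(c / lv**2 for (lv, _), c in cnt.items()) / nr,
        "HighGrayLevelRunEmphasis": sum(c * lv**2 for (lv, _), c in cnt.items()) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(
            c / (lv**2 * ln**2) for (lv, ln), c in cnt.items()
        )
        / nr,
        "ShortRunHighGrayLevelEmphasis": sum(
            c * lv**2 / ln**2 for (lv, ln), c in cnt.items()
        )
        / nr,
        "LongRunLowGrayLevelEmphasis": sum(
            c * ln**2 / lv**2 for (lv, ln), c in cnt.items()
        )
        / nr,
        "LongRunHighGrayLevelEmphasis": sum(
            c * lv**2 * ln**2 for (lv, ln), c in cnt.items()
        )
        / nr,
    }


# ---------------------------------------------------------------------------
# GLSZM (BFS flood fill), GLDM, NGTDM

_NEIGH8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def zones_oracle(levels, mask):
    """(level, size) of every 8-connected equal-level zone, by BFS."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    seen = set()
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or (r, c) in seen:
                continue
            lv = int(levels[r, c])
            stack = [(r, c)]
            seen.add((r, c))
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in _NEIGH8:
                    nr, nc = rr + dr, cc + dc
                    if (
                        0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                        and int(levels[nr, nc]) == lv and (nr, nc) not in seen
                    ):
                        seen.add((nr, nc))
                        stack.append((nr, nc))
            zones.append((lv, size))
    return zones


def glszm_features_oracle(levels, mask):
    n_pix = int(np.asarray(mask, bool).sum())
    zones = zones_oracle(levels, mask)
    nz = len(zones)
    cnt = Counter(zones)
    pi = Counter(lv for lv, _ in zones)
    ps = Counter(s for _, s in zones)
    mu_i = sum(lv * c for lv, c in pi.items()) / nz
    mu_s = sum(s * c for s, c in ps.items()) / nz
    return {
        "SmallAreaEmphasis": sum(c / s**2 for (_, s), c in cnt.items()) / nz,
        "LargeAreaEmphasis": sum(c * s**2 for (_, s), c in cnt.items()) / nz,
        "GrayLevelNonUniformity": sum(c**2 for c in pi.values()) / nz,
        "GrayLevelNonUniformityNormalized": sum(c**2 for c in pi.values()) / nz**2,
        "SizeZoneNonUniformity": sum(c**2 for c in ps.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum(c**2 for c in ps.values()) / nz**2,
        "ZonePercentage": nz / n_pix,
        "GrayLevelVariance": sum((lv - mu_i) ** 2 * c for lv, c in pi.items()) / nz,
        "ZoneVariance": sum((s - mu_s) ** 2 * c for s, c in ps.items()) / nz,
        "ZoneEntropy": -sum((c / nz) * _log2(c / nz) for c in cnt.values()),
        "LowGrayLevelZoneEmphasis": sum(c / lv**2 for (lv, _), c in cnt.items()) / nz,
        "HighGrayLevelZoneEmphasis": sum(c * lv**2 for (lv, _), c in cnt.items()) / nz,
        "SmallAreaLowGrayLevelEmphasis": sum(
            c / (lv**2 * s**2) for (lv, s), c in cnt.items()
        )
        / nz,
        "SmallAreaHighGrayLevelEmphasis": sum(
            c * lv**2 / s**2 for (lv, s), c in cnt.items()
        )
        / nz,
        "LargeAreaLowGrayLevelEmphasis": sum(
            c * s**2 / lv**2 for (lv, s), c in cnt.items()
        )
        / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(
            c * lv**2 * s**2 for (lv, s), c in cnt.items()
        )
        / nz,
    }


def gldm_features_oracle(levels, mask):
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    nv = int(mask.sum())
    cells = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr, dc in _NEIGH8:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and levels[nr, nc] == levels[r, c]:
                    dep += 1
            cells.append((int(levels[r, c]), dep + 1))  # dependence d = count + 1
    cnt = Counter(cells)
    pi = Counter(lv for lv, _ in cells)
    pd = Counter(d for _, d in cells)
    mu_i = sum(lv * c for lv, c in pi.items()) / nv
    mu_d = sum(d * c for d, c in pd.items()) / nv
    return {
        "SmallDependenceEmphasis": sum(c / d**2 for (_, d), c in cnt.items()) / nv,
        "LargeDependenceEmphasis": sum(c * d**2 for (_, d), c in cnt.items()) / nv,
        "GrayLevelNonUniformity": sum(c**2 for c in pi.values()) / nv,
        "DependenceNonUniformity": sum(c**2 for c in pd.values()) / nv,
        "DependenceNonUniformityNormalized": sum(c**2 for c in pd.values()) / nv**2,
        "GrayLevelVariance": sum((lv - mu_i) ** 2 * c for lv, c in pi.items()) / nv,
        "DependenceVariance": sum((d - mu_d) ** 2 * c for d, c in pd.items()) / nv,
        "DependenceEntropy": -sum((c / nv) * _log2(c / nv) for c in cnt.values()),
        "LowGrayLevelEmphasis": sum(c / lv**2 for (lv, _), c in cnt.items()) / nv,
        "HighGrayLevelEmphasis": sum(c * lv**2 for (lv, _), c in cnt.items()) / nv,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            c / (lv**2 * d**2) for (lv, d), c in cnt.items()
        )
        / nv,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            c * lv**2 / d**2 for (lv, d), c in cnt.items()
        )
        / nv,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            c * d**2 / lv**2 for (lv, d), c in cnt.items()
        )
        / nv,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            c * lv**2 * d**2 for (lv, d), c in cnt.items()
        )
        / nv,
    }


def ngtdm_features_oracle(levels, mask):
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    nv = int(mask.sum())
    ng = max(int(levels[r, c]) for r, c in zip(*np.nonzero(mask)))
    s = [0.0] * (ng + 1)
    n = [0] * (ng + 1)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            lv = int(levels[r, c])
            n[lv] += 1
            nb = [
                int(levels[r + dr, c + dc])
                for dr, dc in _NEIGH8
                if 0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
            ]
            if nb:
                s[lv] += abs(lv - sum(nb) / len(nb))
    p = [ni / nv for ni in n]
    present = [i for i in range(1, ng + 1) if p[i] > 0]
    ngp = len(present)
    sum_ps = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * sum(s[i] for i in range(1, ng + 1))
            / nv
        )
    else:
        contrast = 0.0
    denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
    busyness = sum_ps / denom if denom > 0 else 0.0
    complexity = (
        sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present
            for j in present
        )
        / nv
    )
    s_total = sum(s[i] for i in range(1, ng + 1))
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_total
        if s_total > 0
        else 0.0
    )
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# information gain


def information_gain_oracle(x_symbols, y_labels) -> float:
    """IG by exhaustive counting over the joint contingency table."""
    n = len(y_labels)
    y_counts = Counter(y_labels)
    h_y = -sum((c / n) * _log2(c / n) for c in y_counts.values())
    h_cond = 0.0
    for sym in set(x_symbols):
        sub = [y for xv, y in zip(x_symbols, y_labels) if xv == sym]
        m = len(sub)
        sub_counts = Counter(sub)
        h_sub = -sum((c / m) * _log2(c / m) for c in sub_counts.values())
        h_cond += (m / n) * h_sub
    return max(0.0, h_y - h_cond)
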