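"""Gray-level texture matrices and their feature families.

All matrices are built on :class:`~radres.features.preprocess.DiscretizedROI`
(levels 1..N inside the ROI, 0 outside) with the conventional settings:
distance-1 neighbourhoods, the 13 unique 3D directions for co-occurrences
and runs, 26-connectivity for zones, dependences and tone differences.
Raw matrices are integer counts so they can be checked exactly against
brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "glcm_count_matrix",
    "glrlm_count_matrices",
    "glszm_count_matrix",
    "ngtdm_table",
    "gldm_count_matrix",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
]

_EPS = np.spacing(1.0)

#: the 13 unique direction vectors of the 26-neighbourhood (one per
#: antipodal pair; first non-zero component positive)
DIRECTIONS_13: list[tuple[int, int, int]] = [
    d
    for d in (
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    )
    if d != (0, 0, 0) and (d > (0, 0, 0))
]

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _crop_to_roi(disc: DiscretizedROI) -> np.ndarray:
    """Bounding-box crop of the level array (cheap speed-up, no semantics)."""
    lv = disc.levels
    nz = np.nonzero(lv)
    if len(nz[0]) == 0:
        raise ValueError("ROI is empty")
    slices = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    return lv[slices]


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Views (a, b) such that b is arr shifted by +d relative to a."""
    sl_a, sl_b = [], []
    for k, n in zip(d, arr.shape):
        if k >= 0:
            sl_a.append(slice(0, n - k))
            sl_b.append(slice(k, n))
        else:
            sl_a.append(slice(-k, n))
            sl_b.append(slice(0, n + k))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_count_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Symmetric co-occurrence counts summed over the 13 directions
    (each unordered in-ROI voxel pair at Chebyshev distance 1 counted twice)."""
    lv = _crop_to_roi(disc)
    n = disc.n_bins
    mat = np.zeros((n, n), dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _shifted_views(lv, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        codes = (a[valid].astype(np.int64) - 1) * n + (b[valid] - 1)
        counts = np.bincount(codes, minlength=n * n).reshape(n, n)
        mat += counts + counts.T
    return mat


def glcm_features(disc: DiscretizedROI) -> dict[str, float]:
    """24 co-occurrence features from the direction-averaged normalized GLCM."""
    counts = glcm_count_matrix(disc)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid co-occurring voxel pair in the ROI")
    p = counts / total
    n = disc.n_bins
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(px * i))
    uy = float(np.sum(py * i))
    sx = float(np.sqrt(np.sum(px * (i - ux) ** 2)))
    sy = float(np.sqrt(np.sum(py * (i - uy) ** 2)))

    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, n)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    diff_avg = float(np.sum(k_diff * p_diff))
    contrast = float(np.sum(p * (ii - jj) ** 2))
    autocorr = float(np.sum(p * ii * jj))

    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0] + _EPS)))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0] + _EPS)))
    hxy = float(-np.sum(p[p > 0] * np.log2(p[p > 0] + _EPS)))
    pxpy = np.outer(px, py)
    nzp = p > 0
    hxy1 = float(-np.sum(p[nzp] * np.log2(pxpy[nzp] + _EPS)))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2] + _EPS)))
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if sx > 0 and sy > 0:
        correlation = (autocorr - ux * uy) / (sx * sy)
    else:
        correlation = 1.0

    off = np.abs(ii - jj)
    inv_var_mask = off > 0

    # maximal correlation coefficient: second eigenvalue of the transition-like Q
    keep = px > 0
    if keep.sum() < 2:
        mcc = 1.0
    else:
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        pyk = py[keep]
        q = (pk / pxk[:, None]) @ (pk / pyk[:, None]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1]))) if len(eig) > 1 else 1.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": float(np.sum(p * (ii + jj - ux - uy) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - ux - uy) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - ux - uy) ** 2)),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0] + _EPS))),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - diff_avg) ** 2)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / n) ** 2))),
        "Id": float(np.sum(p / (1.0 + off))),
        "Idn": float(np.sum(p / (1.0 + off / n))),
        "InverseVariance": float(np.sum(p[inv_var_mask] / off[inv_var_mask] ** 2)),
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0] + _EPS))),
        "SumSquares": float(np.sum(p * (ii - ux) ** 2)),
    }


GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
]


# ---------------------------------------------------------------------------
# GLRLM

_LINE_ORDER_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _line_order(shape: tuple[int, int, int], d: tuple[int, int, int]):
    """Sorted traversal of the grid grouping voxels by the maximal line they
    lie on along direction ``d``: returns (flat voxel order, new-line flags).
    Cached per (shape, d) — independent of voxel values."""
    key = (shape, d)
    hit = _LINE_ORDER_CACHE.get(key)
    if hit is not None:
        return hit
    idx = np.indices(shape).reshape(3, -1)
    axis = next(k for k in range(3) if d[k] != 0)
    s = idx[axis] * d[axis]  # strictly increasing along the line
    line_key = idx - np.outer(np.array(d), s)
    big = max(shape) * 2 + 2
    scalar = ((line_key[0] + big) * (4 * big) + (line_key[1] + big)) * (4 * big) + (
        line_key[2] + big
    )
    order = np.lexsort((s, scalar))
    new_line = np.empty(order.size, dtype=bool)
    new_line[0] = True
    new_line[1:] = scalar[order][1:] != scalar[order][:-1]
    if len(_LINE_ORDER_CACHE) > 256:
        _LINE_ORDER_CACHE.clear()
    _LINE_ORDER_CACHE[key] = (order, new_line)
    return order, new_line


def glrlm_count_matrices(disc: DiscretizedROI) -> list[np.ndarray]:
    """Per-direction run-length count matrices P[level-1, length-1]."""
    lv = _crop_to_roi(disc)
    n = disc.n_bins
    max_len = int(np.ceil(np.sqrt(np.sum(np.array(lv.shape) ** 2)))) + 1
    flat = lv.ravel()
    mats = []
    for d in DIRECTIONS_13:
        order, new_line = _line_order(lv.shape, d)
        seq = flat[order]
        new_run = new_line.copy()
        new_run[1:] |= seq[1:] != seq[:-1]
        run_id = np.cumsum(new_run) - 1
        lengths = np.bincount(run_id)
        run_levels = seq[new_run]
        keep = run_levels > 0
        mat = np.zeros((n, max_len), dtype=np.int64)
        np.add.at(mat, (run_levels[keep] - 1, lengths[keep] - 1), 1)
        mats.append(mat)
    return mats


def _run_zone_features(mat: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared statistics of run-length / size-zone style matrices."""
    total = mat.sum()
    if total == 0:
        raise ValueError("empty run/zone matrix")
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    gi = mat.sum(axis=1).astype(np.float64)  # per gray level
    rj = mat.sum(axis=0).astype(np.float64)  # per length/size
    p = mat / total
    mu_i = float(np.sum(gi / total * i))
    mu_j = float(np.sum(rj / total * j))
    pnz = p[p > 0]
    inv_j2 = 1.0 / j**2
    inv_i2 = 1.0 / i**2
    f = {
        "Short": float(np.sum(rj * inv_j2) / total),
        "Long": float(np.sum(rj * j**2) / total),
        "GrayLevelNonUniformity": float(np.sum(gi**2) / total),
        "GrayLevelNonUniformityNormalized": float(np.sum(gi**2) / total**2),
        "LengthNonUniformity": float(np.sum(rj**2) / total),
        "LengthNonUniformityNormalized": float(np.sum(rj**2) / total**2),
        "Percentage": float(total / n_voxels),
        "GrayLevelVariance": float(np.sum(gi / total * (i - mu_i) ** 2)),
        "LengthVariance": float(np.sum(rj / total * (j - mu_j) ** 2)),
        "Entropy": float(-np.sum(pnz * np.log2(pnz + _EPS))),
        "LowGrayLevel": float(np.sum(gi * inv_i2) / total),
        "HighGrayLevel": float(np.sum(gi * i**2) / total),
        "ShortLow": float(np.sum(mat * np.outer(inv_i2, inv_j2)) / total),
        "ShortHigh": float(np.sum(mat * np.outer(i**2, inv_j2)) / total),
        "LongLow": float(np.sum(mat * np.outer(inv_i2, j**2)) / total),
        "LongHigh": float(np.sum(mat * np.outer(i**2, j**2)) / total),
    }
    return f


GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

_RL_KEYMAP = {
    "ShortRunEmphasis": "Short", "LongRunEmphasis": "Long",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "LengthNonUniformity",
    "RunLengthNonUniformityNormalized": "LengthNonUniformityNormalized",
    "RunPercentage": "Percentage", "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "LengthVariance", "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevel",
    "HighGrayLevelRunEmphasis": "HighGrayLevel",
    "ShortRunLowGrayLevelEmphasis": "ShortLow",
    "ShortRunHighGrayLevelEmphasis": "ShortHigh",
    "LongRunLowGrayLevelEmphasis": "LongLow",
    "LongRunHighGrayLevelEmphasis": "LongHigh",
}


def glrlm_features(disc: DiscretizedROI) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    n_vox = disc.n_voxels
    per_dir = [_run_zone_features(m, n_vox, "run") for m in glrlm_count_matrices(disc)]
    return {
        name: float(np.mean([f[_RL_KEYMAP[name]] for f in per_dir])) for name in GLRLM_NAMES
    }


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


def glszm_count_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Zone count matrix P[level-1, size-1]; zones are 26-connected
    same-level components."""
    lv = _crop_to_roi(disc)
    n = disc.n_bins
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in np.unique(lv[lv > 0]):
        lab, nlab = ndimage.label(lv == g, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((int(g), int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((n, max_size), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_SZ_KEYMAP = {
    "SmallAreaEmphasis": "Short", "LargeAreaEmphasis": "Long",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "LengthNonUniformity",
    "SizeZoneNonUniformityNormalized": "LengthNonUniformityNormalized",
    "ZonePercentage": "Percentage", "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "LengthVariance", "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevel",
    "HighGrayLevelZoneEmphasis": "HighGrayLevel",
    "SmallAreaLowGrayLevelEmphasis": "ShortLow",
    "SmallAreaHighGrayLevelEmphasis": "ShortHigh",
    "LargeAreaLowGrayLevelEmphasis": "LongLow",
    "LargeAreaHighGrayLevelEmphasis": "LongHigh",
}


def glszm_features(disc: DiscretizedROI) -> dict[str, float]:
    f = _run_zone_features(glszm_count_matrix(disc), disc.n_voxels, "zone")
    return {name: f[_SZ_KEYMAP[name]] for name in GLSZM_NAMES}


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) over ROI voxels that have at least one in-ROI
    26-neighbour; returns (n, s, Nv)."""
    lv = _crop_to_roi(disc).astype(np.float64)
    roi = lv > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(roi.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = roi & (nb_cnt > 0)
    n_bins = disc.n_bins
    n = np.zeros(n_bins, dtype=np.int64)
    s = np.zeros(n_bins, dtype=np.float64)
    levels = lv[valid].astype(int)
    diffs = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n, levels - 1, 1)
    np.add.at(s, levels - 1, diffs)
    return n, s, int(valid.sum())


def ngtdm_features(disc: DiscretizedROI) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    n, s, nv = ngtdm_table(disc)
    if nv == 0:
        raise ValueError("no ROI voxel has an in-ROI neighbour")
    i = np.arange(1, disc.n_bins + 1, dtype=np.float64)
    p = n / nv
    present = p > 0
    ngp = int(present.sum())
    ps = float(np.sum(p * s))

    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp == 1:
        contrast = 0.0
    else:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        di = np.subtract.outer(i, i)
        contrast = float(np.sum(pi * pj * di**2) / (ngp * (ngp - 1)) * (s.sum() / nv))

    ip = i * p
    pairs_i, pairs_j = np.meshgrid(np.arange(disc.n_bins), np.arange(disc.n_bins), indexing="ij")
    both = present[pairs_i] & present[pairs_j]
    denom_bus = float(np.sum(np.abs(np.subtract.outer(ip, ip))[both]))
    busyness = ps / denom_bus if denom_bus > 0 else 0.0

    if ngp > 0:
        psum = np.add.outer(p, p)
        snum = np.add.outer(p * s, p * s)
        absdiff = np.abs(np.subtract.outer(i, i))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(both, absdiff * snum / np.where(psum > 0, psum, 1.0), 0.0)
        complexity = float(term.sum() / nv)
        strength_num = float(np.sum((psum * absdiff**2)[both]))
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:  # pragma: no cover
        complexity, strength = 0.0, 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


# ---------------------------------------------------------------------------
# GLDM


def gldm_count_matrix(disc: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts P[level-1, size-1]; the dependence size of a voxel is
    1 + the number of 26-neighbours inside the ROI with |level diff| <= alpha."""
    lv = _crop_to_roi(disc)
    roi = lv > 0
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        a, b = _shifted_views(lv, d)
        ra, rb = _shifted_views(roi, d)
        sl_a = tuple(
            slice(0, n - k) if k >= 0 else slice(-k, n) for k, n in zip(d, lv.shape)
        )
        dep[sl_a] += (ra & rb & (np.abs(a.astype(np.int64) - b) <= alpha)).astype(np.int64)
    sizes = dep[roi] + 1
    levels = lv[roi]
    mat = np.zeros((disc.n_bins, int(sizes.max())), dtype=np.int64)
    np.add.at(mat, (levels - 1, sizes - 1), 1)
    return mat


GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
]

_DM_KEYMAP = {
    "SmallDependenceEmphasis": "Short", "LargeDependenceEmphasis": "Long",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "DependenceNonUniformity": "LengthNonUniformity",
    "DependenceNonUniformityNormalized": "LengthNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "DependenceVariance": "LengthVariance", "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LowGrayLevel", "HighGrayLevelEmphasis": "HighGrayLevel",
    "SmallDependenceLowGrayLevelEmphasis": "ShortLow",
    "SmallDependenceHighGrayLevelEmphasis": "ShortHigh",
    "LargeDependenceLowGrayLevelEmphasis": "LongLow",
    "LargeDependenceHighGrayLevelEmphasis": "LongHigh",
}


def gldm_features(disc: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    f = _run_zone_features(gldm_count_matrix(disc, alpha=alpha), disc.n_voxels, "dep")
    return {name: f[_DM_KEYMAP[name]] for name in GLDM_NAMES}
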