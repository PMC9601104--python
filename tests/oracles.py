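"""Independent brute-force enumeration oracles for texture matrices and the
greedy selection rule.  Deliberately naive (explicit loops) so they share no
code path with the implementations they check."""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_bruteforce(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Symmetric co-occurrence counts summed over the 13 directions."""
    mat = np.zeros((n_bins, n_bins), dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for d in DIRS_13:
                    q = (x + d[0], y + d[1], z + d[2])
                    if not _inside(shape, q):
                        continue
                    b = levels[q]
                    if b == 0:
                        continue
                    mat[a - 1, b - 1] += 1
                    mat[b - 1, a - 1] += 1
    return mat


def glrlm_bruteforce(levels: np.ndarray, n_bins: int, max_len: int) -> list[np.ndarray]:
    """Per-direction run-length count matrices by explicit line walking."""
    shape = levels.shape
    mats = []
    for d in DIRS_13:
        mat = np.zeros((n_bins, max_len), dtype=np.int64)
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    prev = (x - d[0], y - d[1], z - d[2])
                    v = levels[x, y, z]
                    if v == 0:
                        continue
                    # only start a run where the previous cell breaks it
                    if _inside(shape, prev) and levels[prev] == v:
                        continue
                    length = 1
                    cur = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, cur) and levels[cur] == v:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    mat[v - 1, length - 1] += 1
        mats.append(mat)
    return mats


def glszm_bruteforce(levels: np.ndarray, n_bins: int, max_size: int) -> np.ndarray:
    """Zone counts via breadth-first search over 26-connected same-level sets."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    mat = np.zeros((n_bins, max_size), dtype=np.int64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in OFFS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, q) and not seen[q] and levels[q] == v:
                            seen[q] = True
                            stack.append(q)
                mat[v - 1, size - 1] += 1
    return mat


def ngtdm_bruteforce(levels: np.ndarray, n_bins: int):
    """Per-level (n_i, s_i) with 26-neighbourhood mean differences."""
    shape = levels.shape
    n = np.zeros(n_bins, dtype=np.int64)
    s = np.zeros(n_bins, dtype=np.float64)
    nv = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                nbrs = []
                for d in OFFS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0:
                        nbrs.append(levels[q])
                if not nbrs:
                    continue
                nv += 1
                n[v - 1] += 1
                s[v - 1] += abs(v - sum(nbrs) / len(nbrs))
    return n, s, nv


def gldm_bruteforce(levels: np.ndarray, n_bins: int, max_size: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts: size = 1 + #26-neighbours with |diff| <= alpha."""
    shape = levels.shape
    mat = np.zeros((n_bins, max_size), dtype=np.int64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                dep = 0
                for d in OFFS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(v)) <= alpha:
                        dep += 1
                mat[v - 1, dep] += 1  # size = dep + 1 -> column dep
    return mat


def mrmr_greedy_bruteforce(x: np.ndarray, names: list[str], y: np.ndarray, k: int) -> list[str]:
    """Greedy MIQ selection with per-candidate loops (scipy F, np.corrcoef)."""
    from scipy.stats import f_oneway

    y = np.asarray(y)
    classes = np.unique(y)
    fstats = []
    for j in range(x.shape[1]):
        f = f_oneway(x[y == classes[0], j], x[y == classes[1], j]).statistic
        fstats.append(float(f))
    selected: list[int] = []
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in range(x.shape[1]):
            if j in selected:
                continue
            if not selected:
                score = fstats[j]
            else:
                red = np.mean(
                    [abs(np.corrcoef(x[:, j], x[:, sj])[0, 1]) for sj in selected]
                )
                score = fstats[j] / max(red, 1e-6)
            if score > best_score:  # strict: ties keep the earlier column
                best_j, best_score = j, score
        selected.append(best_j)
    return [names[j] for j in selected]


def random_level_array(rng, n_bins=4, max_side=5) -> np.ndarray:
    """Random small discretized ROI: levels 0..n_bins with background."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(0, n_bins + 1, size=shape)
    if not (levels > 0).any():
        levels.flat[0] = 1
    return levels.astype(np.int32)
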