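"""Independent brute-force oracles for texture matrices and metrics.

Everything here is deliberately naive — explicit Python loops and flood
fills — so the fast implementations can be checked against an independent
construction on small random ROIs.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


def glcm_brute(levels: np.ndarray, roi: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetric normalized GLCM by exhaustive pair enumeration."""
    n = int(levels[roi].max()) + 1
    mat = np.zeros((n, n))
    shape = levels.shape
    for p in np.ndindex(shape):
        if not roi[p] or levels[p] < 0:
            continue
        for d in DIRS_13:
            q = (p[0] + d[0] * distance, p[1] + d[1] * distance, p[2] + d[2] * distance)
            if _in(shape, q) and roi[q] and levels[q] >= 0:
                mat[levels[p], levels[q]] += 1
                mat[levels[q], levels[p]] += 1
    return mat / mat.sum()


def ngldm_brute(levels: np.ndarray, roi: np.ndarray):
    """Per-level probabilities and absolute neighborhood differences."""
    shape = levels.shape
    n = int(levels[roi].max()) + 1
    s = np.zeros(n)
    counts = np.zeros(n)
    for p in np.ndindex(shape):
        if not roi[p] or levels[p] < 0:
            continue
        nb = [
            levels[q]
            for d in NEIGHBORS_26
            if _in(shape, q := (p[0] + d[0], p[1] + d[1], p[2] + d[2]))
            and roi[q] and levels[q] >= 0
        ]
        if not nb:
            continue
        s[levels[p]] += abs(levels[p] - float(np.mean(nb)))
        counts[levels[p]] += 1
    return counts / counts.sum(), s


def glrlm_brute(levels: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Run-length matrix by explicit line scanning along 13 directions."""
    shape = levels.shape
    n = int(levels[roi].max()) + 1
    valid = roi & (levels >= 0)
    mat = np.zeros((n, max(shape)))
    for d in DIRS_13:
        for p in np.ndindex(shape):
            if not valid[p]:
                continue
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _in(shape, prev) and valid[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            while _in(shape, q) and valid[q] and levels[q] == levels[p]:
                length += 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            mat[levels[p], length - 1] += 1
    return mat


def glzlm_brute(levels: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Zone matrix via flood fill over 26-connected equal-level components."""
    shape = levels.shape
    valid = roi & (levels >= 0)
    n = int(levels[roi].max()) + 1
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if not valid[p] or seen[p]:
            continue
        g = levels[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                q = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in(shape, q) and valid[q] and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    mat = np.zeros((n, max(s for _, s in zones)))
    for g, s in zones:
        mat[g, s - 1] += 1
    return mat


def first_order_brute(levels: np.ndarray, roi: np.ndarray) -> dict:
    """Direct-summation histogram statistics."""
    v = levels[roi & (levels >= 0)].astype(float)
    n = len(v)
    mean = v.sum() / n
    var = ((v - mean) ** 2).sum() / n
    if var > 0:
        skew = ((v - mean) ** 3).sum() / n / var ** 1.5
        kurt = ((v - mean) ** 4).sum() / n / var ** 2 - 3.0
    else:
        skew = kurt = 0.0
    _, counts = np.unique(v, return_counts=True)
    p = counts / n
    return {
        "mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt,
        "entropy_log2": float(-(p * np.log2(p)).sum()),
        "energy": float((p ** 2).sum()),
    }


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordant-pair AUC with ties counted one-half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def random_roi(rng: np.random.Generator, max_side: int = 6, n_levels: int = 4):
    """A random small quantized volume and a random nonempty ROI."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(0, n_levels, size=shape).astype(np.int64)
    roi = rng.random(shape) < 0.7
    if not roi.any():
        roi.flat[rng.integers(roi.size)] = True
    return levels, roi
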