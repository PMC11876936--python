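"""Brute-force reference implementations used only by the tests.

Everything here is written as plain enumeration (python loops, BFS
flood fill, O(n^2) pair scans) so it shares no code path with the
vectorized implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_26 = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]

GLCM_DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _in_bounds(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix."""
    shape = levels.shape
    mats = []
    for d in GLCM_DIRECTIONS:
        m = np.zeros((n_levels, n_levels))
        for pos in np.argwhere(mask):
            q = tuple(pos + d)
            if _in_bounds(q, shape) and mask[q]:
                a, b = levels[tuple(pos)] - 1, levels[q] - 1
                m[a, b] += 1
                m[b, a] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    return np.mean(mats, axis=0) if mats else np.zeros((n_levels, n_levels))


def brute_gldm(levels: np.ndarray, mask: np.ndarray, n_levels: int,
               alpha: int = 0) -> np.ndarray:
    m = np.zeros((n_levels, 27))
    for pos in np.argwhere(mask):
        center = levels[tuple(pos)]
        dep = 0
        for d in OFFSETS_26:
            q = tuple(pos + np.array(d))
            if _in_bounds(q, levels.shape) and mask[q] \
                    and abs(int(levels[q]) - int(center)) <= alpha:
                dep += 1
        m[center - 1, dep] += 1
    return m


def brute_glszm_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """All 26-connected equal-level zones via BFS flood fill."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        level = levels[start]
        queue, size = [start], 0
        visited[start] = True
        while queue:
            p = queue.pop()
            size += 1
            for d in OFFSETS_26:
                q = tuple(np.array(p) + d)
                if _in_bounds(q, levels.shape) and mask[q] \
                        and not visited[q] and levels[q] == level:
                    visited[q] = True
                    queue.append(q)
        zones.append((int(level), size))
    return zones


def brute_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    zones = brute_glszm_zones(levels, mask)
    max_size = max(s for _, s in zones)
    m = np.zeros((n_levels, max_size))
    for lv, sz in zones:
        m[lv - 1, sz - 1] += 1
    return m


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level (n_i, s_i) and N_vc by per-voxel neighbour enumeration."""
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    nvc = 0
    for pos in np.argwhere(mask):
        nbrs = []
        for d in OFFSETS_26:
            q = tuple(pos + np.array(d))
            if _in_bounds(q, levels.shape) and mask[q]:
                nbrs.append(int(levels[q]))
        if not nbrs:
            continue
        nvc += 1
        i = int(levels[tuple(pos)])
        n[i - 1] += 1
        s[i - 1] += abs(i - sum(nbrs) / len(nbrs))
    return n, s, nvc


def brute_ngtdm_features(levels, mask, n_levels) -> dict[str, float]:
    n, s, nvc = brute_ngtdm(levels, mask, n_levels)
    p = n / nvc
    idx = [i for i in range(n_levels) if p[i] > 0]
    grays = [i + 1 for i in idx]
    ngp = len(idx)
    ps = sum(p[i] * s[i] for i in idx)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (gi - gj) ** 2
                        for i, gi in zip(idx, grays) for j, gj in zip(idx, grays))
                    / (ngp * (ngp - 1))) * (s.sum() / nvc)
        den = sum(abs(gi * p[i] - gj * p[j])
                  for i, gi in zip(idx, grays) for j, gj in zip(idx, grays))
        busyness = ps / den if den > 0 else 0.0
        complexity = sum(abs(gi - gj) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i, gi in zip(idx, grays)
                         for j, gj in zip(idx, grays)) / nvc
        stot = s.sum()
        strength = (sum((p[i] + p[j]) * (gi - gj) ** 2
                        for i, gi in zip(idx, grays) for j, gj in zip(idx, grays))
                    / stot if stot > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


def brute_firstorder(x: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    x = sorted(float(v) for v in x.ravel())
    n = len(x)
    mean = sum(x) / n
    rng_ = x[-1] - x[0]
    energy = sum(v * v for v in x)
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 - 3.0 if m2 > 0 else 0.0
    if rng_ > 0:
        width = rng_ / n_bins
        counts = [0] * n_bins
        for v in x:
            counts[min(int((v - x[0]) / width), n_bins - 1)] += 1
        entropy = -sum((c / n) * np.log2(c / n) for c in counts if c)
    else:
        entropy = 0.0
    return {"mean": mean, "range": rng_, "energy": energy, "entropy": entropy,
            "skewness": skew, "kurtosis": kurt,
            "p10": float(np.percentile(np.array(x), 10)),
            "p90": float(np.percentile(np.array(x), 90))}


def brute_surface_area(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    sz, sy, sx = spacing
    face = [sy * sx, sz * sx, sz * sy]
    area = 0.0
    for pos in np.argwhere(mask):
        for axis in range(3):
            for sign in (-1, 1):
                q = list(pos)
                q[axis] += sign
                q = tuple(q)
                if not (_in_bounds(q, mask.shape) and mask[q]):
                    area += face[axis]
    return area


def brute_max_diameter(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    pts = [tuple(p * s for p, s in zip(pos, spacing)) for pos in np.argwhere(mask)]
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = sum((a - b) ** 2 for a, b in zip(pts[i], pts[j])) ** 0.5
            best = max(best, d)
    return best


def brute_auc(scores, labels) -> float:
    """Mann–Whitney pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_best_cutoff_objective(scores, labels) -> float:
    """Best sensitivity+specificity over every threshold (exhaustive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    cands = np.r_[scores - 1e-9, scores + 1e-9, scores.min() - 1, scores.max() + 1]
    best = -np.inf
    for c in cands:
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        best = max(best, sens + spec)
    return best


def random_roi(rng: np.random.Generator, max_side: int = 6, n_levels: int = 4):
    """Random small integer-level grid plus a random non-trivial mask."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < rng.uniform(0.3, 0.9)
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask
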