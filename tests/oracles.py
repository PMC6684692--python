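"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written as plain loops / explicit enumeration, on
purpose: these functions must not share code paths with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_bfs(intensity, seed_indices, tolerance_fraction, body=None):
    """Breadth-first 26-connected flood fill with the relative-intensity
    criterion |I(v) - m| <= tol * m, m = mean seed intensity."""
    intensity = np.asarray(intensity, dtype=float)
    m = float(np.mean([intensity[tuple(s)] for s in seed_indices]))
    out = np.zeros(intensity.shape, dtype=bool)

    def ok(i, j, k):
        if body is not None and not body[i, j, k]:
            return False
        return abs(intensity[i, j, k] - m) <= tolerance_fraction * abs(m)

    queue = deque()
    for s in seed_indices:
        s = tuple(int(v) for v in s)
        if ok(*s) and not out[s]:
            out[s] = True
            queue.append(s)
    while queue:
        i, j, k = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (
                        0 <= ni < intensity.shape[0]
                        and 0 <= nj < intensity.shape[1]
                        and 0 <= nk < intensity.shape[2]
                    ):
                        continue
                    if not out[ni, nj, nk] and ok(ni, nj, nk):
                        out[ni, nj, nk] = True
                        queue.append((ni, nj, nk))
    return out


def all_voxels_min_distance(base_world, mask):
    """Exhaustive minimum Euclidean distance from a world point to ANY
    voxel center of the mask (not only boundary voxels)."""
    best = math.inf
    for idx in np.argwhere(mask.voxels):
        p = mask.index_to_world(idx.astype(float))
        d = math.dist(base_world, p)
        if d < best:
            best = d
    return best


def pairwise_concordance_auc(distances, involved):
    """AUC as the pairwise concordance count P(d_pos < d_neg), ties 1/2,
    by explicit double loop."""
    pos = [d for d, y in zip(distances, involved) if y]
    neg = [d for d, y in zip(distances, involved) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_best_youden(distances, involved, convention="le"):
    """(cutoff, J) maximising Youden's J over all observed cut-offs,
    ties toward the smaller cut-off."""
    n1 = sum(involved)
    n0 = len(involved) - n1
    best = (None, -math.inf)
    for t in sorted(set(distances)):
        if convention == "le":
            calls = [d <= t for d in distances]
        else:
            calls = [d < t for d in distances]
        tp = sum(1 for c, y in zip(calls, involved) if c and y)
        fp = sum(1 for c, y in zip(calls, involved) if c and not y)
        j = tp / n1 - fp / n0
        if j > best[1]:
            best = (t, j)
    return best


def ellipsoid_surface_min_distance(point, center, radii, n=1_000_000):
    """Minimum distance to an ellipsoid surface by dense surface sampling."""
    rng = np.random.default_rng(12345)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    surface = np.asarray(center) + np.asarray(radii) * u
    return float(np.min(np.linalg.norm(surface - np.asarray(point), axis=1)))
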