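"""Independent brute-force oracles used by the tests.

These deliberately avoid scipy.ndimage / skimage / statsmodels so they
stay independent of the implementation paths they check.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets_3d(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz, dy, dx in product((-1, 0, 1), repeat=3):
        if (dz, dy, dx) == (0, 0, 0):
            continue
        order = abs(dz) + abs(dy) + abs(dx)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append((dz, dy, dx))
    return offs


def flood_fill_components(
    binary: np.ndarray, connectivity: int = 26
) -> list[set[tuple[int, int, int]]]:
    """BFS connected components of a 3D boolean array."""
    offs = neighbor_offsets_3d(connectivity)
    shape = binary.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            z, y, x = q.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1]
                        and 0 <= n[2] < shape[2]
                        and binary[n] and not seen[n]):
                    seen[n] = True
                    q.append(n)
        comps.append(comp)
    return comps


def border_flood_holes(mask: np.ndarray) -> np.ndarray:
    """Holes of a 2D boolean mask: background not 4-reachable from the border."""
    ny, nx = mask.shape
    outside = np.zeros_like(mask)
    q = deque()
    for y in range(ny):
        for x in (0, nx - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    for x in range(nx):
        for y in (0, ny - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    while q:
        y, x = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny_, nx_ = y + dy, x + dx
            if (0 <= ny_ < ny and 0 <= nx_ < nx
                    and not mask[ny_, nx_] and not outside[ny_, nx_]):
                outside[ny_, nx_] = True
                q.append((ny_, nx_))
    return ~mask & ~outside


def permutation_f_test(samples: list[np.ndarray], n_perm: int, seed: int) -> float:
    """Permutation p-value for the one-way F statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]

    def f_stat(groups):
        grand = np.mean(np.concatenate(groups))
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
        dfb = len(groups) - 1
        dfw = sum(sizes) - len(groups)
        return (ssb / dfb) / (ssw / dfw)

    obs = f_stat(samples)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for k in sizes:
            parts.append(perm[start:start + k])
            start += k
        if f_stat(parts) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def permutation_pair_test(a: np.ndarray, b: np.ndarray, n_perm: int, seed: int) -> float:
    """Permutation p-value for |mean difference| between two samples."""
    rng = np.random.default_rng(seed)
    obs = abs(np.mean(a) - np.mean(b))
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(np.mean(perm[:len(a)]) - np.mean(perm[len(a):])) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
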