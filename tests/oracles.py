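"""Independent brute-force oracles for the texture-matrix tests.

Everything here is written as plain Python loops over voxels, deliberately
sharing no code with the package implementation: pair enumeration for the
co-occurrence matrix, forward run-walking for the run-length matrix,
breadth-first flood fill for the size-zone matrix, and an explicit
neighborhood loop for the gray-tone difference matrix.
"""

from __future__ import annotations

import numpy as np

# one representative per +/- offset pair, lexicographically positive
OFFSETS = [(dx, dy, dz)
           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
           if (dx, dy, dz) > (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def glcm_oracle(levels: np.ndarray, n_levels: int, distance: int = 1) -> np.ndarray:
    """Symmetric pair counts over 13 offsets, both orderings."""
    shape = levels.shape
    counts = np.zeros((n_levels, n_levels))
    voxels = list(zip(*np.nonzero(levels)))
    for (dx, dy, dz) in OFFSETS:
        off = (dx * distance, dy * distance, dz * distance)
        for v in voxels:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _inside(shape, w) and levels[w] > 0:
                a, b = levels[v] - 1, levels[w] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def glrlm_oracle(levels: np.ndarray, n_levels: int, directions=None) -> np.ndarray:
    """Run counts by walking each direction from every run start."""
    dirs = directions if directions is not None else OFFSETS
    shape = levels.shape
    runs = []
    for d in dirs:
        for v in zip(*np.nonzero(levels)):
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _inside(shape, prev) and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _inside(shape, w) and levels[w] == levels[v]:
                length += 1
                w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
            runs.append((levels[v], length))
    max_len = max(max(shape), max(l for _, l in runs))
    counts = np.zeros((n_levels, max_len))
    for g, l in runs:
        counts[g - 1, l - 1] += 1
    return counts


def glszm_oracle(levels: np.ndarray, n_levels: int) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level zone, by flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    nbrs = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]
    zones = []
    for v in zip(*np.nonzero(levels)):
        if seen[v]:
            continue
        g = levels[v]
        stack, size = [v], 0
        seen[v] = True
        while stack:
            u = stack.pop()
            size += 1
            for d in nbrs:
                w = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if _inside(shape, w) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(g), size))
    return sorted(zones)


def ngtdm_oracle(levels: np.ndarray, n_levels: int):
    """(n_i, s_i) per level with explicit 26-neighborhood loops."""
    shape = levels.shape
    nbrs = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for v in zip(*np.nonzero(levels)):
        vals = []
        for d in nbrs:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and levels[w] > 0:
                vals.append(levels[w])
        if not vals:
            continue
        g = levels[v]
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(vals) / len(vals))
    return n, s


def random_quantized_roi(rng: np.random.Generator, n_levels: int = 6,
                         max_side: int = 8):
    """A random small level array (0 = outside ROI) for oracle comparisons."""
    shape = tuple(int(rng.integers(3, max_side)) for _ in range(3))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(c // 2 for c in shape)] = True
    levels[~mask] = 0
    return levels
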