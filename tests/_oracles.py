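"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: plain loops and
all-pairs computations only, kept separate so that a bug in the library
cannot hide inside its own reference values.
"""

from __future__ import annotations

import numpy as np


def band_counts(data: np.ndarray, grid, n_level: float) -> list[int]:
    """Voxel count per candidate band by explicit per-voxel comparison."""
    i_max = float(max(data.flat))
    counts = []
    for th in grid:
        lo = (th - n_level) * i_max
        hi = th * i_max
        c = 0
        for v in data.flat:
            if lo < v < hi:
                c += 1
        counts.append(c)
    return counts


def triangle_bin(hist: np.ndarray) -> int:
    """Triangle-method bin by exhaustive point-to-line distance search.

    Returns the index of the bin with maximal perpendicular distance to the
    line joining the histogram peak and the far end of the longer tail.
    """
    hist = np.asarray(hist, dtype=float)
    nonzero = [i for i, h in enumerate(hist) if h > 0]
    first, last = nonzero[0], nonzero[-1]
    peak = int(np.argmax(hist))
    end = last if (last - peak) >= (peak - first) else first
    if end == peak:
        return peak
    x0, y0 = float(peak), float(hist[peak])
    x1, y1 = float(end), float(hist[end])
    length = np.hypot(x1 - x0, y1 - y0)
    best, best_d = None, -1.0
    lo, hi = (peak, end) if end > peak else (end, peak)
    for i in range(lo, hi + 1):
        d = abs((y1 - y0) * i - (x1 - x0) * hist[i] + x1 * y0 - y1 * x0) / length
        if d > best_d:
            best_d = d
            best = i
    return best


def euclidean_distance_map(mask: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance to the nearest background voxel.

    Everything outside the array is background: the candidate distances are
    all in-array background voxels plus, per axis, the nearest voxel of the
    virtual background layer wrapping the array.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    fg = np.argwhere(mask)
    for idx in fg:
        border = min(
            min(idx[a] + 1, mask.shape[a] - idx[a]) for a in range(mask.ndim)
        )
        if len(bg):
            diffs = bg - idx
            inner = np.sqrt((diffs**2).sum(axis=1).min())
            out[tuple(idx)] = min(inner, border)
        else:
            out[tuple(idx)] = border
    return out


def block_means_loop(data: np.ndarray, block: int = 3) -> np.ndarray:
    """Per-block averaging with explicit loops and edge replication."""
    shape = data.shape
    grid_shape = tuple(-(-s // block) for s in shape)
    out = np.zeros(grid_shape, dtype=float)
    for gz in range(grid_shape[0]):
        for gy in range(grid_shape[1]):
            for gx in range(grid_shape[2]):
                vals = []
                for dz in range(block):
                    for dy in range(block):
                        for dx in range(block):
                            z = min(gz * block + dz, shape[0] - 1)
                            y = min(gy * block + dy, shape[1] - 1)
                            x = min(gx * block + dx, shape[2] - 1)
                            vals.append(float(data[z, y, x]))
                out[gz, gy, gx] = sum(vals) / len(vals)
    return out


def ball_mask(radius: float, pad: int = 2) -> np.ndarray:
    """Digital ball: voxel centres within ``radius`` of the centre."""
    n = int(np.ceil(radius)) * 2 + 1 + 2 * pad
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def monolayer_cluster_centres(k: int, r: float, seed: int) -> list[np.ndarray]:
    """Random fused-cluster centres with >= 1.5 r spacing, roughly coplanar
    (adherent monolayer geometry)."""
    rng = np.random.default_rng(seed)
    centres = [np.zeros(3)]
    while len(centres) < k:
        base = centres[rng.integers(len(centres))]
        d = rng.uniform(1.5 * r, 1.9 * r)
        phi = rng.uniform(0, 2 * np.pi)
        v = np.array([rng.uniform(-0.2, 0.2), np.sin(phi), np.cos(phi)])
        v /= np.linalg.norm(v)
        cand = base + d * v
        if all(np.linalg.norm(cand - c) >= 1.5 * r for c in centres):
            centres.append(cand)
    return centres
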