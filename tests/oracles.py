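"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: border adjacency by
per-pixel neighbour enumeration, ribbon construction by all-pairs
Chebyshev distance, and shell classification by a dense rasterized
distance transform.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt


def brute_force_borders(labels: np.ndarray, cid: int):
    """(outer, internal) pixel sets of one cell by direct enumeration."""
    outer, internal = set(), set()
    h, w = labels.shape

    def neighbours(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                yield labels[rr, cc] if 0 <= rr < h and 0 <= cc < w else 0

    for r in range(h):
        for c in range(w):
            if labels[r, c] != cid:
                continue
            neigh = list(neighbours(r, c))
            if all(n == cid for n in neigh):
                continue
            if any(n != cid and n > 0 for n in neigh):
                internal.add((r, c))
            else:
                outer.add((r, c))
    return outer, internal


def brute_force_ribbon(labels: np.ndarray, outer_pixels, cid: int, width: int):
    """Ribbon pixel set by all-pairs Chebyshev distance."""
    h, w = labels.shape
    outer_pixels = [tuple(p) for p in outer_pixels]
    ribbon = set()
    for r in range(h):
        for c in range(w):
            if labels[r, c] not in (0, cid):
                continue
            for br, bc in outer_pixels:
                if max(abs(r - br), abs(c - bc)) <= width:
                    ribbon.add((r, c))
                    break
    return ribbon


def raster_boundary_distances(
    boundary: np.ndarray, points: np.ndarray, grid_nm: float = 10.0
) -> np.ndarray:
    """Distance of each point to the polygon curve via a dense raster EDT.

    The polygon edge is sampled at sub-grid resolution onto a boolean
    raster; an EDT of its complement gives the distance field. Accuracy is
    limited by the grid (about half a grid step).
    """
    closed = np.vstack([boundary, boundary[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    samples = [closed[:-1]]
    for i, L in enumerate(seg_len):
        n = max(int(np.ceil(L / (grid_nm / 4.0))), 1)
        t = np.arange(1, n)[:, None] / n
        samples.append(closed[i] + t * seg[i])
    pts_curve = np.vstack(samples)

    allpts = np.vstack([pts_curve, points])
    lo = allpts.min(axis=0) - 5 * grid_nm
    hi = allpts.max(axis=0) + 5 * grid_nm
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / grid_nm)) + 1 for k in (0, 1))
    raster = np.zeros(shape, dtype=bool)
    idx = np.round((pts_curve - lo) / grid_nm).astype(int)
    raster[idx[:, 0], idx[:, 1]] = True
    dist = distance_transform_edt(~raster) * grid_nm
    pidx = np.round((points - lo) / grid_nm).astype(int)
    return dist[pidx[:, 0], pidx[:, 1]]
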