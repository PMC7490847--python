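"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (python loops, sets, explicit
matrix algebra) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# TFCE: per-threshold connected components by breadth-first search
# ---------------------------------------------------------------------------

def _neighbors(connectivity: int):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def brute_force_tfce(stat: np.ndarray, dh: float, h_exp: float, e_exp: float,
                     connectivity: int = 26) -> np.ndarray:
    """TFCE by explicit per-threshold BFS component labeling."""
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    peak = stat.max()
    if peak <= 0:
        return out
    offsets = _neighbors(connectivity)
    shape = stat.shape
    h = dh
    while h <= peak + 1e-12:
        supra = stat >= h
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            # BFS flood fill of the component containing `start`.
            comp = [start]
            seen[start] = True
            queue = [start]
            while queue:
                cx, cy, cz = queue.pop()
                for dx, dy, dz in offsets:
                    nx, ny, nz = cx + dx, cy + dy, cz + dz
                    if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                            and 0 <= nz < shape[2] and supra[nx, ny, nz]
                            and not seen[nx, ny, nz]):
                        seen[nx, ny, nz] = True
                        comp.append((nx, ny, nz))
                        queue.append((nx, ny, nz))
            add = len(comp) ** e_exp * h**h_exp * dh
            for v in comp:
                out[v] += add
        h += dh
    return out


# ---------------------------------------------------------------------------
# Single-fiber column: exhaustive path enumeration in deterministic mode
# ---------------------------------------------------------------------------

def column_enumeration_counts(streamlines, grid_shape, affine, wm_mask, step: float):
    """Recompute visited-voxel counts for straight +/-z column streamlines.

    For every retained streamline the full deterministic path is rebuilt
    from one endpoint by naive stepping until the white-matter column is
    left, then supersampled at half steps and binned with python sets.
    """
    inv = np.linalg.inv(affine)
    shape = tuple(int(s) for s in grid_shape)
    counts = np.zeros(shape, dtype=np.int64)

    def voxel(p):
        c = inv[:3, :3] @ p + inv[:3, 3]
        return tuple(int(round(x)) for x in c)

    for sl in streamlines:
        start = np.asarray(sl.points[0], dtype=float)
        path = [start]
        pos = start.copy()
        while True:
            nxt = pos + np.array([0.0, 0.0, step])
            v = voxel(nxt)
            if not all(0 <= v[i] < shape[i] for i in range(3)) or not wm_mask[v]:
                break
            path.append(nxt)
            pos = nxt
        dense = []
        for a, b in zip(path[:-1], path[1:]):
            dense.append(a)
            dense.append(0.5 * (a + b))
        dense.append(path[-1])
        visited = {voxel(p) for p in dense}
        for v in visited:
            counts[v] += 1
    return counts


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def naive_partial_correlation(x, y, Z):
    """Residualize with explicit normal equations, correlate with loops."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    A = np.column_stack([np.ones(n), np.asarray(Z, float)])
    bx = np.linalg.inv(A.T @ A) @ (A.T @ x)
    by = np.linalg.inv(A.T @ A) @ (A.T @ y)
    rx = x - A @ bx
    ry = y - A @ by
    num = sum(a * b for a, b in zip(rx, ry))
    den = np.sqrt(sum(a * a for a in rx) * sum(b * b for b in ry))
    return num / den


def projection_f_test(y, X_full, X_reduced):
    """F statistic from explicit hat matrices."""
    y = np.asarray(y, float)

    def rss(X):
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        r = y - H @ y
        return float(r @ r)

    rss_f = rss(X_full)
    rss_r = rss(X_reduced)
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = len(y) - X_full.shape[1]
    return ((rss_r - rss_f) / df1) / (rss_f / df2)
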