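"""Independent brute-force oracles used to check the implementation.

Every function here is deliberately naive — exhaustive search, explicit
python loops, full enumeration — and shares no code with the package paths
it verifies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_otsu(values: np.ndarray) -> int:
    """Exhaustive Otsu for 8-bit data: try all 256 thresholds, maximize
    between-class variance, smallest threshold on ties."""
    v = np.asarray(values).ravel().astype(np.float64)
    best_t, best_var = None, -1.0
    for t in range(256):
        bg = v[v <= t]
        fg = v[v > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size / v.size, fg.size / v.size
        var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def loop_count(support: np.ndarray, connectivity: int = 8, min_focus_px: int = 1) -> int:
    """Connected components by explicit flood fill."""
    comps = loop_components(support, connectivity)
    return sum(1 for c in comps if len(c) >= min_focus_px)


def loop_components(support: np.ndarray, connectivity: int = 8):
    support = np.asarray(support, dtype=bool)
    h, w = support.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(support)
    comps = []
    for r in range(h):
        for c in range(w):
            if support[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and support[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def loop_area(support: np.ndarray, connectivity: int = 8, min_focus_px: int = 1) -> int:
    return sum(len(c) for c in loop_components(support, connectivity) if len(c) >= min_focus_px)


def loop_intensity(grid: np.ndarray) -> float:
    total = 0
    h, w = grid.shape
    for r in range(h):
        for c in range(w):
            total += int(grid[r, c]) if np.issubdtype(grid.dtype, np.integer) else float(grid[r, c])
    return total


def enumerate_rank_sum_p(x, y) -> tuple:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Tie-free samples only.  Returns (U of x, p)."""
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    n1, n2 = len(x), len(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_of(group):
        rest = [v for v in pooled if v not in group]
        return sum(1 for a in group for b in rest if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    u_low = min(u_obs, n1 * n2 - u_obs)
    u_high = max(u_obs, n1 * n2 - u_obs)
    n_extreme = 0
    total = 0
    for combo in itertools.combinations(pooled, n1):
        u = u_of(set(combo))
        total += 1
        if u <= u_low or u >= u_high:
            n_extreme += 1
    return u_obs, min(1.0, n_extreme / total)


def fcm_restart_objective(
    x, c: int, m: float = 2.0, n_restarts: int = 30, seed: int = 0, n_iter: int = 500
) -> float:
    """Best (smallest) FCM objective over random restarts.

    Independent plain per-point implementation on intensities normalized to
    [0, 1], matching the package's objective scale.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    xs = (x - lo) / (hi - lo)
    rng = np.random.default_rng(seed)
    uniq = np.unique(xs)
    best = math.inf
    for _ in range(n_restarts):
        v = np.sort(rng.choice(uniq, size=c, replace=False))
        for _ in range(n_iter):
            d = np.abs(xs[:, None] - v[None, :])
            d = np.maximum(d, 1e-15)
            u = (d ** (-2.0 / (m - 1.0)))
            u = u / u.sum(axis=1, keepdims=True)
            um = u**m
            v_new = (um * xs[:, None]).sum(axis=0) / um.sum(axis=0)
            if np.max(np.abs(v_new - v)) < 1e-12:
                v = v_new
                break
            v = v_new
        d = np.abs(xs[:, None] - v[None, :])
        obj = float(((u**m) * d**2).sum())
        best = min(best, obj)
    return best
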