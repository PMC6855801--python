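"""Brute-force oracles, independent of the library implementations.

These recompute segmentation and counting operations by direct definition
(python flood fill, per-voxel loops, exact rational enumeration) so the
vectorised implementations can be checked against first principles.
"""

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def hysteresis_flood_fill(img: np.ndarray, low: float, high: float, connectivity: int = 26):
    """Direct definition: BFS from >= high voxels through >= low voxels."""
    img = np.asarray(img, dtype=float)
    mask = np.zeros(img.shape, dtype=bool)
    offs = neighbor_offsets(connectivity)
    shape = img.shape
    q = deque()
    for idx in np.argwhere(img >= high):
        t = tuple(int(i) for i in idx)
        if not mask[t]:
            mask[t] = True
            q.append(t)
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offs:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if not mask[nz, ny, nx] and img[nz, ny, nx] >= low:
                    mask[nz, ny, nx] = True
                    q.append((nz, ny, nx))
    return mask


def count_voxels_loop(labels: np.ndarray) -> int:
    """Per-voxel foreground count by explicit loop."""
    n = 0
    for v in labels.ravel():
        if v > 0:
            n += 1
    return n


def intersection_loop(a: np.ndarray, b: np.ndarray) -> int:
    """Per-voxel AND count by explicit loop."""
    n = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        if va > 0 and vb > 0:
            n += 1
    return n


def fisher_two_sided_rational(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    total = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), total)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), total)
        if pk <= p_obs:
            p += pk
    return float(p)


def ols_normal_equations(x, y):
    """Closed-form OLS slope/intercept/r²/two-sided slope-t p."""
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    m = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    b = (sy - m * sx) / n
    resid = y - (m * x + b)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / ((x - x.mean()) ** 2).sum())
    t = m / se
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return m, b, r2, p
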