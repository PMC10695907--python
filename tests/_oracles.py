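"""Independent brute-force reference implementations used only by tests.

Deliberately written with primitive array shifts, breadth-first search and
direct pairwise-comparison definitions so they share no code path with the
package implementations they check.
"""

from collections import deque
from itertools import combinations

import numpy as np


def _shift(data: np.ndarray, off) -> np.ndarray:
    """Translate a boolean array by ``off``, filling with background."""
    out = np.zeros_like(data)
    src = []
    dst = []
    for axis, o in enumerate(off):
        n = data.shape[axis]
        src.append(slice(max(0, -o), n - max(0, o)))
        dst.append(slice(max(0, o), n - max(0, -o)))
    out[tuple(dst)] = data[tuple(src)]
    return out


def _offsets(se: np.ndarray):
    center = tuple(s // 2 for s in se.shape)
    return [tuple(i - c for i, c in zip(idx, center))
            for idx in np.argwhere(se)]


def brute_dilate(data: np.ndarray, se: np.ndarray) -> np.ndarray:
    out = np.zeros_like(data)
    for off in _offsets(se):
        out |= _shift(data, off)
    return out


def brute_erode(data: np.ndarray, se: np.ndarray) -> np.ndarray:
    out = np.ones_like(data)
    for off in _offsets(se):
        out &= _shift(data, tuple(-o for o in off))
    return out


def _pad(data: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(data, pad, constant_values=False)


def _crop(data: np.ndarray, pad: int) -> np.ndarray:
    return data[pad:-pad, pad:-pad, pad:-pad]


def brute_close(data: np.ndarray, se: np.ndarray, iterations: int = 1) -> np.ndarray:
    pad = max(se.shape) // 2 * iterations + 1
    work = _pad(data, pad)
    for _ in range(iterations):
        work = brute_dilate(work, se)
    for _ in range(iterations):
        work = brute_erode(work, se)
    return _crop(work, pad)


def brute_open(data: np.ndarray, se: np.ndarray, iterations: int = 1) -> np.ndarray:
    pad = max(se.shape) // 2 * iterations + 1
    work = _pad(data, pad)
    for _ in range(iterations):
        work = brute_erode(work, se)
    for _ in range(iterations):
        work = brute_dilate(work, se)
    return _crop(work, pad)


def _neighbor_offsets(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def brute_fill_holes(data: np.ndarray, background_connectivity: int = 6) -> np.ndarray:
    """Flood-fill the background from the border; everything unreached is a hole."""
    dims = data.shape
    reached = np.zeros(dims, dtype=bool)
    queue = deque()
    for idx in np.ndindex(dims):
        if any(i == 0 or i == n - 1 for i, n in zip(idx, dims)) and not data[idx]:
            if not reached[idx]:
                reached[idx] = True
                queue.append(idx)
    offs = _neighbor_offsets(background_connectivity)
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offs:
            nz, ny, nx = z + dz, y + dy, x + dx
            if (0 <= nz < dims[0] and 0 <= ny < dims[1] and 0 <= nx < dims[2]
                    and not data[nz, ny, nx] and not reached[nz, ny, nx]):
                reached[nz, ny, nx] = True
                queue.append((nz, ny, nx))
    return data | ~(data | reached)


def brute_component_count(data: np.ndarray, connectivity: int) -> int:
    """Count foreground components by breadth-first flood fill."""
    dims = data.shape
    seen = np.zeros(dims, dtype=bool)
    offs = _neighbor_offsets(connectivity)
    count = 0
    for start in np.ndindex(dims):
        if not data[start] or seen[start]:
            continue
        count += 1
        seen[start] = True
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (0 <= nz < dims[0] and 0 <= ny < dims[1] and 0 <= nx < dims[2]
                        and data[nz, ny, nx] and not seen[nz, ny, nx]):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return count


def _u_of_subset(pooled, subset):
    """U statistic of ``subset`` vs the rest, by direct pairwise comparison."""
    rest = [v for i, v in enumerate(pooled) if i not in subset]
    chosen = [pooled[i] for i in subset]
    u = 0.0
    for a in chosen:
        for b in rest:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def enumerate_mw_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    pooled = list(a) + list(b)
    n_a, n_b = len(a), len(b)
    u_obs = _u_of_subset(pooled, set(range(n_a)))
    total = 0
    tail_lo = 0
    tail_hi = 0
    for subset in combinations(range(n_a + n_b), n_a):
        total += 1
        u = _u_of_subset(pooled, set(subset))
        if u <= u_obs + 1e-9:
            tail_lo += 1
        if u >= u_obs - 1e-9:
            tail_hi += 1
    return min(1.0, 2.0 * min(tail_lo, tail_hi) / total)
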