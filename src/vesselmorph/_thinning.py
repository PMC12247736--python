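"""Topology-preserving 3D medial-axis thinning.

Distance-ordered directional thinning: the mask is peeled shell by shell
in increasing order of the (static) distance transform, and within each
shell by subiterations over the six face directions, deleting only
*simple* points (points whose removal changes neither the 26-connected
foreground topology nor the 6-connected background topology) that are
not line endpoints. The distance ordering keeps the skeleton on the
ridge of the distance transform — the medial axis of a tube — while the
directional subiterations keep the peeling symmetric and preserve line
tips. Candidates are collected per subiteration and then rechecked
sequentially against the partially thinned image, so every deletion is
of a point that is simple at deletion time — topology preservation is
exact by construction.

Point simplicity uses the classical two-condition characterization for
(26, 6) digital topology: exactly one 26-connected foreground component
in the punctured 3x3x3 neighborhood, and exactly one 6-connected
background component in the 18-neighborhood touching a face neighbour.

The inner loops are numba-compiled; thinning a 128^3 vessel phantom
takes well under a second after JIT warm-up.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage


@njit(cache=True)
def _count_fg_neighbors(nb):
    n = 0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                if nb[i, j, k] != 0 and not (i == 1 and j == 1 and k == 1):
                    n += 1
    return n


@njit(cache=True)
def _is_simple(nb):
    """Simple-point test on a 3x3x3 neighborhood (center at [1,1,1])."""
    # condition A: exactly one 26-connected foreground component among
    # the 26 neighbours (center excluded)
    visited = np.zeros((3, 3, 3), np.uint8)
    stack = np.empty((27, 3), np.int8)
    n_fg_comp = 0
    for i0 in range(3):
        for j0 in range(3):
            for k0 in range(3):
                if i0 == 1 and j0 == 1 and k0 == 1:
                    continue
                if nb[i0, j0, k0] == 0 or visited[i0, j0, k0] != 0:
                    continue
                n_fg_comp += 1
                if n_fg_comp > 1:
                    return False
                top = 0
                stack[top, 0], stack[top, 1], stack[top, 2] = i0, j0, k0
                top += 1
                visited[i0, j0, k0] = 1
                while top > 0:
                    top -= 1
                    ci, cj, ck = stack[top, 0], stack[top, 1], stack[top, 2]
                    for di in range(-1, 2):
                        for dj in range(-1, 2):
                            for dk in range(-1, 2):
                                ni, nj, nk = ci + di, cj + dj, ck + dk
                                if ni < 0 or ni > 2 or nj < 0 or nj > 2 or nk < 0 or nk > 2:
                                    continue
                                if ni == 1 and nj == 1 and nk == 1:
                                    continue
                                if nb[ni, nj, nk] != 0 and visited[ni, nj, nk] == 0:
                                    visited[ni, nj, nk] = 1
                                    stack[top, 0], stack[top, 1], stack[top, 2] = ni, nj, nk
                                    top += 1
    if n_fg_comp != 1:
        return False

    # condition B: exactly one 6-connected background component in the
    # 18-neighborhood reachable from a background face neighbour
    for i in range(3):
        for j in range(3):
            for k in range(3):
                visited[i, j, k] = 0
    n_bg_comp = 0
    for t in range(6):
        i0 = 1 + (1 if t == 0 else -1 if t == 1 else 0)
        j0 = 1 + (1 if t == 2 else -1 if t == 3 else 0)
        k0 = 1 + (1 if t == 4 else -1 if t == 5 else 0)
        if nb[i0, j0, k0] != 0 or visited[i0, j0, k0] != 0:
            continue
        n_bg_comp += 1
        if n_bg_comp > 1:
            return False
        top = 0
        stack[top, 0], stack[top, 1], stack[top, 2] = i0, j0, k0
        top += 1
        visited[i0, j0, k0] = 1
        while top > 0:
            top -= 1
            ci, cj, ck = stack[top, 0], stack[top, 1], stack[top, 2]
            for d in range(6):
                ni = ci + (1 if d == 0 else -1 if d == 1 else 0)
                nj = cj + (1 if d == 2 else -1 if d == 3 else 0)
                nk = ck + (1 if d == 4 else -1 if d == 5 else 0)
                if ni < 0 or ni > 2 or nj < 0 or nj > 2 or nk < 0 or nk > 2:
                    continue
                if ni == 1 and nj == 1 and nk == 1:
                    continue
                # stay inside the 18-neighborhood (exclude corners)
                if abs(ni - 1) + abs(nj - 1) + abs(nk - 1) > 2:
                    continue
                if nb[ni, nj, nk] == 0 and visited[ni, nj, nk] == 0:
                    visited[ni, nj, nk] = 1
                    stack[top, 0], stack[top, 1], stack[top, 2] = ni, nj, nk
                    top += 1
    return n_bg_comp == 1


#: subiteration border directions (up, down, north, south, east, west)
_DIRECTIONS = (
    (0, 0, 1),
    (0, 0, -1),
    (0, 1, 0),
    (0, -1, 0),
    (1, 0, 0),
    (-1, 0, 0),
)


@njit(cache=True)
def _subiteration(img, pts, di, dj, dk):
    """One directional peel: collect candidates, then sequential recheck."""
    n = pts.shape[0]
    cand = np.empty((n, 3), np.int64)
    m = 0
    for t in range(n):
        i, j, k = pts[t, 0], pts[t, 1], pts[t, 2]
        if img[i + di, j + dj, k + dk] != 0:  # not a border point this direction
            continue
        nb = img[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2]
        if _count_fg_neighbors(nb) < 2:  # endpoint or isolated: keep
            continue
        if _is_simple(nb):
            cand[m, 0], cand[m, 1], cand[m, 2] = i, j, k
            m += 1
    deleted = 0
    for t in range(m):
        i, j, k = cand[t, 0], cand[t, 1], cand[t, 2]
        nb = img[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2]
        if _count_fg_neighbors(nb) >= 2 and _is_simple(nb):
            img[i, j, k] = 0
            deleted += 1
    return deleted


def compute_thin_image(mask: np.ndarray) -> np.ndarray:
    """Thin a 3D binary array to a one-voxel-wide, topology-equivalent skeleton."""
    if mask.ndim != 3:
        raise ValueError("thinning expects a 3D binary array")
    img = np.pad(np.ascontiguousarray(mask, dtype=np.uint8), 1)
    if img.max() == 0:
        return np.zeros(mask.shape, dtype=bool)
    # static deletion priority: distance to background in the original mask
    edt = ndimage.distance_transform_edt(img)
    levels = np.unique(np.ceil(edt[img > 0]))
    for level in levels:
        eligible = edt <= level
        while True:
            deleted = 0
            for di, dj, dk in _DIRECTIONS:
                pts = np.argwhere((img == 1) & eligible)
                if len(pts) == 0:
                    break
                deleted += _subiteration(img, pts, di, dj, dk)
            if deleted == 0:
                break
    return img[1:-1, 1:-1, 1:-1].astype(bool)
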