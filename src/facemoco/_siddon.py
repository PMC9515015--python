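"""Numba kernels: exact radiological-path (Siddon-style) ray tracing and its
adjoint, plus batch drivers for list-mode forward/back-projection.

Grid convention matches :class:`facemoco.volume.ImageVolume`: voxel (i,j,k)
is centered at origin + (i,j,k)*spacing, so the grid's outer boundary lies
half a voxel beyond the first/last centers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True, fastmath=True)
def _ray_setup(p1, p2, origin, spacing, shape):
    """Clip segment p1->p2 to the grid; returns (ok, a_min, a_max, length)."""
    a_min = 0.0
    a_max = 1.0
    length = 0.0
    for ax in range(3):
        d = p2[ax] - p1[ax]
        length += d * d
        lo = origin[ax] - 0.5 * spacing[ax]
        hi = origin[ax] + (shape[ax] - 0.5) * spacing[ax]
        if abs(d) < _EPS:
            if p1[ax] <= lo or p1[ax] >= hi:
                return False, 0.0, 0.0, 0.0
        else:
            a0 = (lo - p1[ax]) / d
            a1 = (hi - p1[ax]) / d
            if a0 > a1:
                a0, a1 = a1, a0
            if a0 > a_min:
                a_min = a0
            if a1 < a_max:
                a_max = a1
    length = np.sqrt(length)
    if a_min >= a_max:
        return False, 0.0, 0.0, 0.0
    return True, a_min, a_max, length


@njit(cache=True, fastmath=True)
def trace_ray(vol, origin, spacing, p1, p2, backproject, value):
    """March the clipped segment voxel by voxel.

    forward (``backproject=False``): returns sum(vol[v] * intersection_mm).
    adjoint (``backproject=True``): vol[v] += value * intersection_mm, for
    the identical intersection lengths; returns 0.
    """
    shape = vol.shape
    ok, a_min, a_max, length = _ray_setup(p1, p2, origin, spacing, shape)
    if not ok:
        return 0.0

    # entry point and per-axis parametric steps
    ijk = np.empty(3, dtype=np.int64)
    a_next = np.empty(3)
    da = np.empty(3)
    step = np.empty(3, dtype=np.int64)
    for ax in range(3):
        d = p2[ax] - p1[ax]
        x = p1[ax] + a_min * d
        f = (x - (origin[ax] - 0.5 * spacing[ax])) / spacing[ax]
        i = int(np.floor(f))
        if i < 0:
            i = 0
        if i > shape[ax] - 1:
            i = shape[ax] - 1
        ijk[ax] = i
        if abs(d) < _EPS:
            step[ax] = 0
            da[ax] = 1e30
            a_next[ax] = 1e30
        else:
            if d > 0:
                step[ax] = 1
                nxt = origin[ax] + (i + 0.5) * spacing[ax]
            else:
                step[ax] = -1
                nxt = origin[ax] + (i - 0.5) * spacing[ax]
            da[ax] = spacing[ax] / abs(d)
            a_next[ax] = (nxt - p1[ax]) / d

    total = 0.0
    a_cur = a_min
    while a_cur < a_max - _EPS:
        # next crossing
        ax_min = 0
        if a_next[1] < a_next[ax_min]:
            ax_min = 1
        if a_next[2] < a_next[ax_min]:
            ax_min = 2
        a_stop = a_next[ax_min]
        if a_stop > a_max:
            a_stop = a_max
        seg = (a_stop - a_cur) * length
        if seg > 0.0:
            if backproject:
                vol[ijk[0], ijk[1], ijk[2]] += value * seg
            else:
                total += vol[ijk[0], ijk[1], ijk[2]] * seg
        a_cur = a_stop
        ijk[ax_min] += step[ax_min]
        a_next[ax_min] += da[ax_min]
        if ijk[ax_min] < 0 or ijk[ax_min] >= shape[ax_min]:
            break
    return total


@njit(cache=True, fastmath=True)
def forward_project_events(vol, origin, spacing, p1s, p2s, out):
    for i in range(p1s.shape[0]):
        out[i] = trace_ray(vol, origin, spacing, p1s[i], p2s[i], False, 0.0)


@njit(cache=True, fastmath=True)
def backproject_events(values, origin, spacing, p1s, p2s, out_vol):
    for i in range(p1s.shape[0]):
        trace_ray(out_vol, origin, spacing, p1s[i], p2s[i], True, values[i])
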