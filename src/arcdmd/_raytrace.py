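"""Exact ray-grid traversal kernels (Amanatides-Woo DDA), numba-compiled.

Two primitives on a regular grid whose voxel (i, j, k) is the axis-aligned
box centred at ``origin + (i, j, k) * spacing``:

* ``ray_integrals`` - exact line integral of a piecewise-constant scalar
  field along the segment source -> point (sum of per-voxel chord length x
  voxel value).  Used for radiological path length.
* ``ray_hits`` - does the ray from the source through a point intersect any
  nonzero voxel of a binary mask?  Used for divergent beam's-eye-view
  silhouettes (a BEV pixel lies inside a voxel's projected footprint iff
  the source->pixel ray intersects the voxel cube).

Both are exact up to floating point; there is no step-size parameter.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-9


@njit(cache=True, fastmath=True)
def _slab_clip(src, d, lo, hi):
    """Clip parameter range of p(t) = src + t*d to the box [lo, hi].

    Returns (t0, t1); empty intersection iff t0 > t1.
    """
    t0 = 0.0
    t1 = np.inf
    for a in range(3):
        if abs(d[a]) < _EPS:
            if src[a] < lo[a] or src[a] > hi[a]:
                return 1.0, 0.0
        else:
            ta = (lo[a] - src[a]) / d[a]
            tb = (hi[a] - src[a]) / d[a]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True, fastmath=True)
def _traverse_integral(values, spacing, origin, src, pt):
    d = pt - src
    length = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
    if length < _EPS:
        return 0.0
    lo = np.empty(3)
    hi = np.empty(3)
    for a in range(3):
        lo[a] = origin[a] - 0.5 * spacing[a]
        hi[a] = origin[a] + (values.shape[a] - 0.5) * spacing[a]
    t0, t1 = _slab_clip(src, d, lo, hi)
    if t1 <= t0:
        return 0.0
    if t1 > 1.0:
        t1 = 1.0  # integrate only up to the endpoint
    if t0 >= t1:
        return 0.0

    # Entry voxel (nudged inside).
    idx = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    step = np.empty(3, dtype=np.int64)
    t_start = t0 + _EPS * (t1 - t0)
    for a in range(3):
        p = src[a] + t_start * d[a]
        i = int(np.floor((p - lo[a]) / spacing[a]))
        if i < 0:
            i = 0
        if i >= values.shape[a]:
            i = values.shape[a] - 1
        idx[a] = i
        if d[a] > _EPS:
            step[a] = 1
            t_max[a] = ((lo[a] + (i + 1) * spacing[a]) - src[a]) / d[a]
            t_delta[a] = spacing[a] / d[a]
        elif d[a] < -_EPS:
            step[a] = -1
            t_max[a] = ((lo[a] + i * spacing[a]) - src[a]) / d[a]
            t_delta[a] = -spacing[a] / d[a]
        else:
            step[a] = 0
            t_max[a] = np.inf
            t_delta[a] = np.inf

    acc = 0.0
    t = t0
    while t < t1:
        a_min = 0
        if t_max[1] < t_max[a_min]:
            a_min = 1
        if t_max[2] < t_max[a_min]:
            a_min = 2
        t_next = t_max[a_min]
        if t_next > t1:
            t_next = t1
        acc += values[idx[0], idx[1], idx[2]] * (t_next - t)
        t = t_next
        if t >= t1:
            break
        idx[a_min] += step[a_min]
        if idx[a_min] < 0 or idx[a_min] >= values.shape[a_min]:
            break
        t_max[a_min] += t_delta[a_min]
    return acc * length


@njit(cache=True, fastmath=True)
def _traverse_hit(mask, spacing, origin, src, d):
    lo = np.empty(3)
    hi = np.empty(3)
    for a in range(3):
        lo[a] = origin[a] - 0.5 * spacing[a]
        hi[a] = origin[a] + (mask.shape[a] - 0.5) * spacing[a]
    t0, t1 = _slab_clip(src, d, lo, hi)
    if t1 <= t0:
        return False
    if t0 < 0.0:
        t0 = 0.0

    idx = np.empty(3, dtype=np.int64)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    step = np.empty(3, dtype=np.int64)
    t_start = t0 + _EPS * (t1 - t0 + 1.0)
    for a in range(3):
        p = src[a] + t_start * d[a]
        i = int(np.floor((p - lo[a]) / spacing[a]))
        if i < 0:
            i = 0
        if i >= mask.shape[a]:
            i = mask.shape[a] - 1
        idx[a] = i
        if d[a] > _EPS:
            step[a] = 1
            t_max[a] = ((lo[a] + (i + 1) * spacing[a]) - src[a]) / d[a]
            t_delta[a] = spacing[a] / d[a]
        elif d[a] < -_EPS:
            step[a] = -1
            t_max[a] = ((lo[a] + i * spacing[a]) - src[a]) / d[a]
            t_delta[a] = -spacing[a] / d[a]
        else:
            step[a] = 0
            t_max[a] = np.inf
            t_delta[a] = np.inf

    t = t0
    while t < t1:
        if mask[idx[0], idx[1], idx[2]]:
            return True
        a_min = 0
        if t_max[1] < t_max[a_min]:
            a_min = 1
        if t_max[2] < t_max[a_min]:
            a_min = 2
        t = t_max[a_min]
        idx[a_min] += step[a_min]
        if idx[a_min] < 0 or idx[a_min] >= mask.shape[a_min]:
            break
        t_max[a_min] += t_delta[a_min]
    return False


@njit(cache=True, fastmath=True)
def ray_integrals(values, spacing, origin, src, pts):
    """Line integral of ``values`` along each segment src -> pts[i] (mm units)."""
    n = pts.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _traverse_integral(values, spacing, origin, src, pts[i])
    return out


@njit(cache=True, fastmath=True)
def ray_hits(mask, spacing, origin, src, dirs):
    """True where the ray src + t*dirs[i] (t >= 0) crosses a nonzero voxel."""
    n = dirs.shape[0]
    out = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        out[i] = _traverse_hit(mask, spacing, origin, src, dirs[i])
    return out
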