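"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-voxel loops, exhaustive
enumeration, closed forms) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- plan-quality indices (exhaustive voxel loops) --------------------------

def _vox_cc(grid) -> float:
    dx, dy, dz = grid.spacing
    return dx * dy * dz / 1000.0


def _count(pred) -> int:
    n = 0
    nx, ny, nz = pred.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if pred[i, j, k]:
                    n += 1
    return n


def oracle_indices(dose: np.ndarray, rx: float, ptv: np.ndarray, body: np.ndarray, grid) -> dict:
    """CI, CN, R50, C_delta and their component volumes by exhaustive count."""
    cc = _vox_cc(grid)
    tv = _count(ptv) * cc
    piv = _count((dose >= rx) & body) * cc
    tv_piv = _count((dose >= rx) & body & ptv) * cc
    v50 = _count((dose >= 0.5 * rx) & body) * cc
    return {
        "ci": piv / tv,
        "cn": tv_piv**2 / (tv * piv),
        "r50": v50 / tv,
        "c_delta": (piv - tv_piv) / tv,
        "tv_cc": tv,
        "piv_cc": piv,
        "tv_piv_cc": tv_piv,
        "v50_cc": v50,
    }


def oracle_d2cm(dose: np.ndarray, rx: float, ptv: np.ndarray, body: np.ndarray, grid) -> float:
    """Max dose >= 20 mm from the PTV, by a per-voxel distance loop."""
    sp = np.asarray(grid.spacing)
    ptv_idx = np.argwhere(ptv)
    best = -np.inf
    for v in np.argwhere(body):
        d2 = np.min(np.sum(((ptv_idx - v) * sp) ** 2, axis=1))
        if d2 >= 20.0**2 and dose[tuple(v)] > best:
            best = dose[tuple(v)]
    return best / rx * 100.0


def oracle_lung(dose: np.ndarray, lung: np.ndarray, itv: np.ndarray) -> tuple[float, float, float]:
    sel = lung & ~itv
    vals = [dose[tuple(v)] for v in np.argwhere(sel)]
    n = len(vals)
    v20 = sum(1 for v in vals if v >= 20.0) / n * 100.0
    v2_5 = sum(1 for v in vals if v >= 2.5) / n * 100.0
    return v20, v2_5, float(np.mean(vals))


def oracle_percentile_dx(doses_in_mask: np.ndarray, x_percent: float) -> float:
    """Dose received by >= x% of the volume: sorted-sample linear quantile."""
    return float(np.quantile(np.sort(doses_in_mask), 1.0 - x_percent / 100.0))


# -- hot/cold classification ------------------------------------------------

def oracle_hot_cold(dose: np.ndarray, ptv: np.ndarray, body: np.ndarray, rx: float):
    hot = np.zeros_like(ptv)
    cold = np.zeros_like(ptv)
    nx, ny, nz = ptv.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if dose[i, j, k] >= rx and not ptv[i, j, k] and body[i, j, k]:
                    hot[i, j, k] = True
                if dose[i, j, k] < rx and ptv[i, j, k]:
                    cold[i, j, k] = True
    return hot, cold


# -- statistics -------------------------------------------------------------

def oracle_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank p by full 2^n sign enumeration (midranks for ties)."""
    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = []
    for signs in itertools.product([0, 1], repeat=n):
        sums.append(sum(r for s, r in zip(signs, ranks) if s))
    sums = np.asarray(sums)
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(w_obs), min(1.0, 2.0 * min(p_le, p_ge))


def oracle_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks."""
    from scipy.stats import rankdata

    rx_, ry = rankdata(x), rankdata(y)
    rx_ = rx_ - rx_.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx_ * ry) / np.sqrt(np.sum(rx_**2) * np.sum(ry**2)))


# -- geometry ---------------------------------------------------------------

def oracle_footprint_open(
    pixel_xy: np.ndarray,
    voxel_indices: np.ndarray,
    grid,
    src: np.ndarray,
    iso: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
) -> np.ndarray:
    """Exact divergent silhouette: ray-AABB slab test per (pixel, voxel)."""
    sp = np.asarray(grid.spacing)
    org = np.asarray(grid.origin)
    lo = org + voxel_indices * sp - sp / 2.0  # (M, 3)
    hi = lo + sp
    targets = iso + pixel_xy[:, 0:1] * e1 + pixel_xy[:, 1:2] * e2  # (P, 3)
    d = targets - src  # (P, 3)
    open_px = np.zeros(len(pixel_xy), dtype=bool)
    for m in range(len(voxel_indices)):
        t0 = np.full(len(pixel_xy), -np.inf)
        t1 = np.full(len(pixel_xy), np.inf)
        ok = np.ones(len(pixel_xy), dtype=bool)
        for a in range(3):
            da = d[:, a]
            par = np.abs(da) < 1e-12
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (lo[m, a] - src[a]) / da
                tb = (hi[m, a] - src[a]) / da
            lo_t = np.minimum(ta, tb)
            hi_t = np.maximum(ta, tb)
            t0 = np.where(par, t0, np.maximum(t0, lo_t))
            t1 = np.where(par, t1, np.minimum(t1, hi_t))
            ok &= ~par | ((src[a] >= lo[m, a]) & (src[a] <= hi[m, a]))
        open_px |= ok & (t1 >= np.maximum(t0, 0.0))
    return open_px
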