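"""Plan-quality indices for SBRT: RTOG 0915 / Paddick / ICRU suite plus lung dose.

All isodose volumes are voxel-centre counts with a ">= threshold"
convention (one shared cc-conversion routine), restricted to tissue (the
body mask) so that dose deposited in surrounding air never inflates an
index.  Relative indices are computed on dose normalized to the
prescription; lung metrics use absolute Gy.

Indices
-------
CI          V_Rx / V_PTV                       (RTOG conformity index, ideal 1)
CI_Paddick  TV_PIV^2 / (TV * PIV)              (conformity number, ideal 1)
R50%        V_50%Rx / V_PTV                    (gradient index)
D2cm        max dose >= 2 cm from the PTV surface, as % of Rx
HI          (D2% - D98%) / D50%                (target homogeneity, ideal 0)
C_delta     (V_PI - PTV_PI) / V_PTV            (external index: healthy tissue at Rx)
Lung        V20Gy %, V2.5Gy %, mean lung dose (Gy) on lungs minus ITV
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .dose_engine import DoseGrid
from .phantom import FractionationScheme, ImageGrid, StructureSet, mask_volume_cc
from .planning import DVH, compute_dvh

__all__ = [
    "PlanMetrics",
    "MetricsError",
    "conformity_index",
    "paddick_cn",
    "gradient_r50",
    "d2cm",
    "homogeneity_index",
    "external_index",
    "lung_metrics",
    "evaluate_plan",
]


class MetricsError(ValueError):
    pass


def _dose_values(dose: DoseGrid | ImageGrid | np.ndarray) -> np.ndarray:
    if isinstance(dose, DoseGrid):
        return dose.grid.values
    if isinstance(dose, ImageGrid):
        return dose.values
    return np.asarray(dose)


def _isodose_mask(dose, level: float, body: np.ndarray | None) -> np.ndarray:
    m = _dose_values(dose) >= level
    if body is not None:
        m = m & np.asarray(body, dtype=bool)
    return m


def conformity_index(dose, rx: float, ptv: np.ndarray, grid: ImageGrid,
                     body: np.ndarray | None = None) -> float:
    """RTOG conformity index: prescription isodose volume over PTV volume."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise MetricsError("empty PTV")
    v_rx = mask_volume_cc(_isodose_mask(dose, rx, body), grid)
    return v_rx / mask_volume_cc(ptv, grid)


def paddick_cn(dose, rx: float, ptv: np.ndarray, grid: ImageGrid,
               body: np.ndarray | None = None) -> tuple[float, dict]:
    """Paddick conformity number with its TV / PIV / TV_PIV components (cc)."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise MetricsError("empty PTV")
    piv_mask = _isodose_mask(dose, rx, body)
    tv = mask_volume_cc(ptv, grid)
    piv = mask_volume_cc(piv_mask, grid)
    tv_piv = mask_volume_cc(ptv & piv_mask, grid)
    if piv == 0:
        raise MetricsError("prescription isodose volume is empty")
    return tv_piv**2 / (tv * piv), {"tv_cc": tv, "piv_cc": piv, "tv_piv_cc": tv_piv}


def gradient_r50(dose, rx: float, ptv: np.ndarray, grid: ImageGrid,
                 body: np.ndarray | None = None) -> tuple[float, float]:
    """R50%: half-prescription isodose volume over PTV volume; returns (R50, V50 cc)."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise MetricsError("empty PTV")
    v50 = mask_volume_cc(_isodose_mask(dose, 0.5 * rx, body), grid)
    return v50 / mask_volume_cc(ptv, grid), v50


def d2cm(dose, rx: float, ptv: np.ndarray, body: np.ndarray, grid: ImageGrid,
         distance_mm: float = 20.0) -> float:
    """Max dose (% of Rx) in tissue at >= 2 cm Euclidean distance from the PTV."""
    ptv = np.asarray(ptv, dtype=bool)
    body = np.asarray(body, dtype=bool)
    dist = ndimage.distance_transform_edt(~ptv, sampling=grid.spacing)
    shell = body & (dist >= distance_mm)
    if not shell.any():
        raise MetricsError("phantom too small: no tissue >= 2 cm from PTV")
    return float(_dose_values(dose)[shell].max() / rx * 100.0)


def homogeneity_index(dvh: DVH) -> float:
    """HI = (D2% - D98%) / D50% from the target DVH."""
    d50 = dvh.d50
    if d50 == 0:
        raise MetricsError("D50% is zero")
    return (dvh.d2 - dvh.d98) / d50


def external_index(dose, rx: float, ptv: np.ndarray, grid: ImageGrid,
                   body: np.ndarray | None = None) -> float:
    """C_delta = (V_PI - PTV_PI) / V_PTV: healthy-tissue share of the Rx isodose."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise MetricsError("empty PTV")
    piv_mask = _isodose_mask(dose, rx, body)
    v_pi = mask_volume_cc(piv_mask, grid)
    ptv_pi = mask_volume_cc(piv_mask & ptv, grid)
    return (v_pi - ptv_pi) / mask_volume_cc(ptv, grid)


def lung_metrics(dose_gy, lung_mask: np.ndarray, itv: np.ndarray | None,
                 grid: ImageGrid, exclude_itv: bool = True) -> tuple[float, float, float]:
    """Lung V20Gy (%), V2.5Gy (%), and mean lung dose (Gy).

    Computed on the lung volume minus the ITV by default (the common
    "lung minus GTV/ITV" clinical convention); set ``exclude_itv=False``
    to evaluate whole lungs.
    """
    lung = np.asarray(lung_mask, dtype=bool)
    if exclude_itv and itv is not None:
        lung = lung & ~np.asarray(itv, dtype=bool)
    if not lung.any():
        raise MetricsError("empty lung")
    d = _dose_values(dose_gy)[lung]
    v20 = float(np.count_nonzero(d >= 20.0) / d.size * 100.0)
    v2_5 = float(np.count_nonzero(d >= 2.5) / d.size * 100.0)
    return v20, v2_5, float(d.mean())


@dataclass
class PlanMetrics:
    """All evaluation indices of one plan (relative ones on the Rx scale)."""

    ci: float
    cn_paddick: float
    tv_cc: float
    piv_cc: float
    tv_piv_cc: float
    r50: float
    v50_cc: float
    d2cm_pct: float
    hi: float
    d2_pct: float
    d50_pct: float
    d98_pct: float
    c_delta: float
    ptv_dmax_pct: float
    ptv_dmean_pct: float
    coverage_fraction: float
    lung_v20_pct: float
    lung_v2_5_pct: float
    mld_gy: float

    def to_dict(self) -> dict:
        return asdict(self)

    # Table-style column order used by the cohort report.
    COLUMNS = (
        "ci", "cn_paddick", "r50", "d2cm_pct", "hi", "c_delta",
        "ptv_dmax_pct", "ptv_dmean_pct", "d2_pct", "d98_pct",
        "lung_v20_pct", "lung_v2_5_pct", "mld_gy", "coverage_fraction",
    )


def evaluate_plan(
    dose: DoseGrid | ImageGrid,
    structures: StructureSet,
    prescription: FractionationScheme | float,
    target_name: str = "ptv",
    exclude_itv_from_lung: bool = True,
) -> PlanMetrics:
    """Aggregate every index for one normalized (absolute-Gy) dose grid."""
    rx = prescription.total_gy if isinstance(prescription, FractionationScheme) else float(prescription)
    grid = structures.grid
    ptv = structures[target_name]
    body = structures["body"]
    dvals = _dose_values(dose)

    ci = conformity_index(dvals, rx, ptv, grid, body)
    cn, comps = paddick_cn(dvals, rx, ptv, grid, body)
    r50, v50 = gradient_r50(dvals, rx, ptv, grid, body)
    d2 = d2cm(dvals, rx, ptv, body, grid)
    dvh = compute_dvh(grid.with_values(dvals), ptv, structure=target_name)
    hi = homogeneity_index(dvh)
    cdelta = external_index(dvals, rx, ptv, grid, body)
    v20, v2_5, mld = lung_metrics(dvals, structures.lungs, structures["itv"], grid,
                                  exclude_itv=exclude_itv_from_lung)
    return PlanMetrics(
        ci=ci,
        cn_paddick=cn,
        tv_cc=comps["tv_cc"],
        piv_cc=comps["piv_cc"],
        tv_piv_cc=comps["tv_piv_cc"],
        r50=r50,
        v50_cc=v50,
        d2cm_pct=d2,
        hi=hi,
        d2_pct=dvh.d2 / rx * 100.0,
        d50_pct=dvh.d50 / rx * 100.0,
        d98_pct=dvh.d98 / rx * 100.0,
        c_delta=cdelta,
        ptv_dmax_pct=dvh.dmax / rx * 100.0,
        ptv_dmean_pct=dvh.dmean / rx * 100.0,
        coverage_fraction=dvh.vx(rx),
        lung_v20_pct=v20,
        lung_v2_5_pct=v2_5,
        mld_gy=mld,
    )
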