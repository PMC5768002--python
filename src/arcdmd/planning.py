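"""Conventional dynamic-conformal-arc planning and prescription normalization.

A DCA plan carries one MLC aperture per arc control point, each fitted to
the divergent BEV silhouette of the target at that gantry angle (0 mm
margin by default).  After 3-D dose computation, the prescription isodose
is normalized to cover 95 % of the target: dose scaling is linear, so the
scale is exactly Rx / D95.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dose_engine import DoseGrid
from .geometry import ArcSpec, BeamGeometry, ControlPointAperture, bev_project, fit_mlc, make_arc
from .phantom import FractionationScheme, ImageGrid, StructureSet

__all__ = ["Plan", "DVH", "PlanningError", "plan_dca", "normalize_to_coverage", "compute_dvh"]


class PlanningError(ValueError):
    pass


@dataclass
class Plan:
    """Arc + per-control-point apertures + prescription + normalization."""

    arc: ArcSpec
    geometry: BeamGeometry
    apertures: list[ControlPointAperture]
    target_name: str
    prescription: FractionationScheme
    normalization_scale: float = 1.0
    bev_pitch_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.normalization_scale <= 0:
            raise PlanningError("normalization scale must be positive")
        if len(self.apertures) != self.arc.n_control_points:
            raise PlanningError(
                f"{len(self.apertures)} apertures != {self.arc.n_control_points} arc control points"
            )

    def to_json(self, path: str | Path) -> None:
        d = {
            "arc": {
                "span_deg": self.arc.span_deg,
                "control_point_spacing_deg": self.arc.control_point_spacing_deg,
                "gap_center_deg": self.arc.gap_center_deg,
                "direction": self.arc.direction,
            },
            "geometry": {
                "sad_mm": self.geometry.sad_mm,
                "leaf_width_iso_mm": self.geometry.leaf_width_iso_mm,
                "n_leaf_pairs": self.geometry.n_leaf_pairs,
                "isocenter_mm": list(self.geometry.isocenter_mm),
            },
            "target_name": self.target_name,
            "prescription": {
                "dose_per_fraction_gy": self.prescription.dose_per_fraction_gy,
                "n_fractions": self.prescription.n_fractions,
            },
            "normalization_scale": self.normalization_scale,
            "bev_pitch_mm": self.bev_pitch_mm,
            "apertures": [a.to_dict() for a in self.apertures],
        }
        Path(path).write_text(json.dumps(d))


def mask_centroid(mask: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """World-mm centroid of a binary mask (voxel-centre mean)."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise PlanningError("empty mask has no centroid")
    return np.asarray(grid.origin) + idx.mean(axis=0) * np.asarray(grid.spacing)


def fit_arc_apertures(
    mask: np.ndarray,
    grid: ImageGrid,
    geometry: BeamGeometry,
    angles: np.ndarray,
    margin_mm: float,
    bev_pitch_mm: float,
) -> list[ControlPointAperture]:
    return [
        fit_mlc(
            bev_project(mask, grid, geometry, g, pitch_mm=bev_pitch_mm),
            geometry,
            margin_mm,
            gantry_deg=g,
        )
        for g in angles
    ]


def plan_dca(
    structures: StructureSet,
    target_name: str,
    arc: ArcSpec,
    geometry: BeamGeometry,
    margin_mm: float = 0.0,
    prescription: FractionationScheme | None = None,
    isocenter_mm: np.ndarray | None = None,
    bev_pitch_mm: float = 1.0,
) -> Plan:
    """Build a conventional DCA plan: apertures track the target's BEV.

    The isocenter defaults to the target centroid; pass ``isocenter_mm`` to
    keep a previously chosen isocenter (e.g. when re-planning on a deformed
    target).
    """
    if target_name not in structures or not structures[target_name].any():
        raise PlanningError(f"target {target_name!r} is empty or missing")
    mask = structures[target_name]
    if isocenter_mm is None:
        isocenter_mm = mask_centroid(mask, structures.grid)
    geometry = geometry.with_isocenter(np.asarray(isocenter_mm))
    angles = make_arc(arc)
    apertures = fit_arc_apertures(mask, structures.grid, geometry, angles, margin_mm, bev_pitch_mm)
    if prescription is None:
        prescription = FractionationScheme(18.0, 3)
    return Plan(arc, geometry, apertures, target_name, prescription, 1.0, bev_pitch_mm)


@dataclass
class NormalizationResult:
    dose: DoseGrid  # scaled dose, Gy
    scale: float  # multiplier applied to the input dose
    rx_isodose_level: float  # Rx as a fraction of the scaled maximum dose


def normalize_to_coverage(
    dose: DoseGrid | ImageGrid,
    target_mask: np.ndarray,
    prescription: FractionationScheme | float,
    coverage_fraction: float = 0.95,
) -> NormalizationResult:
    """Scale a dose so the prescription covers >= 95 % of the target.

    The smallest such scale is Rx / D95 where D95 is the k-th smallest
    in-target voxel dose with k = floor(0.05 N) + 1: the resulting covered
    fraction lies in [0.95, 0.95 + 1/N] for distinct voxel doses.  Raises
    "coverage unattainable" if more than 5 % of the target receives no dose.
    """
    grid = dose.grid if isinstance(dose, DoseGrid) else dose
    rx = prescription.total_gy if isinstance(prescription, FractionationScheme) else float(prescription)
    target_mask = np.asarray(target_mask, dtype=bool)
    d = grid.values[target_mask]
    if d.size == 0:
        raise PlanningError("empty target")
    if np.count_nonzero(d <= 0) > (1.0 - coverage_fraction) * d.size:
        raise PlanningError("coverage unattainable")
    k = int(np.floor((1.0 - coverage_fraction) * d.size)) + 1
    k = min(k, d.size)
    d_cov = np.partition(d, k - 1)[k - 1]
    scale = rx / d_cov
    # float guard: the covering voxel itself must land at >= rx after scaling
    while d_cov * scale < rx:
        scale = np.nextafter(scale, np.inf)
    scaled = grid.with_values(grid.values * scale)
    return NormalizationResult(
        dose=DoseGrid(scaled, "Gy"),
        scale=float(scale),
        rx_isodose_level=float(rx / scaled.values.max()),
    )


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    Statistics are computed on the sorted voxel doses directly (the binned
    curve is for export/plotting).  Dx = dose received by at least x % of
    the volume; Vx = fraction of the volume receiving >= x.
    """

    structure: str
    dose_edges: np.ndarray  # Gy (or engine units)
    cum_volume: np.ndarray  # fraction of structure volume at >= edge
    _sorted_doses: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def dx(self, x_percent: float) -> float:
        """Dose received by at least ``x_percent`` % of the volume."""
        return float(np.quantile(self._sorted_doses, 1.0 - x_percent / 100.0))

    def vx(self, dose: float) -> float:
        """Fraction of the volume receiving at least ``dose``."""
        return float(np.count_nonzero(self._sorted_doses >= dose) / self._sorted_doses.size)

    @property
    def d2(self) -> float:
        return self.dx(2.0)

    @property
    def d50(self) -> float:
        return self.dx(50.0)

    @property
    def d98(self) -> float:
        return self.dx(98.0)

    @property
    def dmax(self) -> float:
        return float(self._sorted_doses[-1])

    @property
    def dmean(self) -> float:
        return float(self._sorted_doses.mean())

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"dose": self.dose_edges, "fractional_volume": self.cum_volume}).to_csv(
            path, index=False
        )


def compute_dvh(
    dose: DoseGrid | ImageGrid, mask: np.ndarray, n_bins: int = 2000, structure: str = ""
) -> DVH:
    """Cumulative DVH by voxel counting; bin width max(0.1 Gy, Dmax / n_bins)."""
    grid = dose.grid if isinstance(dose, DoseGrid) else dose
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PlanningError("empty mask")
    d = np.sort(grid.values[mask])
    dmax = d[-1]
    width = max(0.1, dmax / n_bins) if dmax > 0 else 0.1
    edges = np.arange(0.0, dmax + width, width)
    # V(edge) = fraction of voxels with dose >= edge; V(0) = 1.
    cum = 1.0 - np.searchsorted(d, edges, side="left") / d.size
    cum[0] = 1.0
    return DVH(structure, edges, cum, _sorted_doses=d)
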