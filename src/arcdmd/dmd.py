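"""Deformable margin delineation (DMD) for dynamic conformal arcs.

Conformal-arc plans on non-spherical lung targets show a characteristic
failure mode: tissue just outside the planning target receives the full
prescription (hot sleeves where the arc's aperture union over-covers the
target's short axis) while parts of the target itself fall below the
prescription (cold tips where penumbra acts from every gantry angle).
The DMD method fixes this by editing the *aperture-fitting* target, not
the prescription: regions outside the PTV at >= 100 % of the prescription
drive local shrinkage of the fitting target, regions inside the PTV below
100 % drive local expansion.  The MLC is refitted to the deformed target,
dose is recomputed, and the prescription isodose is renormalized to cover
95 % of the ORIGINAL PTV -- coverage is therefore never traded away; only
conformity changes.

In the clinic this deformation is a manual, slice-by-slice contouring
exercise.  Here it is automated as a morphological update: hot/cold
regions are dilated by one step, applied only within a surface band of the
current target (a distant hot island can never punch a hole through the
interior), and the result is smoothed by a small morphological closing.
Iteration stops when the residual hot and cold volumes fall below a
tolerance or a maximum round count; the returned plan is the iteration
with the conformity index closest to unity (ties go to fewer rounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dose_engine import ArcDoseEngine, BeamModel, DoseGrid
from .geometry import ArcSpec, BeamGeometry, make_arc
from .metrics import PlanMetrics, evaluate_plan
from .phantom import FractionationScheme, ImageGrid, StructureSet, mask_volume_cc
from .planning import (
    Plan,
    PlanningError,
    fit_arc_apertures,
    mask_centroid,
    normalize_to_coverage,
)

__all__ = ["HotColdRegions", "DMDParams", "DMDResult", "DMDError",
           "find_hot_cold", "deform_target", "run_dmd"]


class DMDError(ValueError):
    pass


@dataclass
class HotColdRegions:
    """Rx-level misdose regions of a normalized plan.

    hot:  dose >= Rx, outside the original PTV, inside the body.
    cold: dose <  Rx, inside the original PTV.
    """

    hot: np.ndarray
    cold: np.ndarray
    hot_cc: float
    cold_cc: float


@dataclass(frozen=True)
class DMDParams:
    """Automation parameters of the deformation loop.

    step_mm
        Deformation magnitude per iteration; ``None`` means one voxel
        (the largest grid spacing).
    max_iters
        Maximum number of deformation rounds (baseline excluded).
    stop_tol_cc
        Stop when both hot and cold volumes fall below this (cc); the
        default 0.2 cc is below the discretization noise of a 2 mm grid.
    smooth_radius_mm
        Radius of the morphological closing applied after each update.
    require_itv
        If True (default) the deformed target is never shrunk below the ITV.
    """

    step_mm: float | None = None
    max_iters: int = 10
    stop_tol_cc: float = 0.2
    smooth_radius_mm: float = 2.0
    require_itv: bool = True

    def __post_init__(self) -> None:
        if self.step_mm is not None and self.step_mm <= 0:
            raise DMDError("step must be positive")
        if self.max_iters < 1:
            raise DMDError("max_iters must be >= 1")


def find_hot_cold(
    dose: DoseGrid | ImageGrid | np.ndarray,
    ptv: np.ndarray,
    body: np.ndarray,
    rx: float,
    grid: ImageGrid,
) -> HotColdRegions:
    """Voxelwise hot/cold classification of a normalized dose against the PTV."""
    d = dose.values if isinstance(dose, (DoseGrid, ImageGrid)) else np.asarray(dose)
    ptv = np.asarray(ptv, dtype=bool)
    body = np.asarray(body, dtype=bool)
    hot = (d >= rx) & ~ptv & body
    cold = (d < rx) & ptv
    return HotColdRegions(hot, cold, mask_volume_cc(hot, grid), mask_volume_cc(cold, grid))


def _dilate(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Euclidean dilation by a ball of ``radius_mm`` (anisotropy honoured)."""
    if radius_mm <= 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def _close(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    if radius_mm <= 0 or not mask.any():
        return mask.copy()
    dilated = _dilate(mask, radius_mm, spacing)
    return ~_dilate(~dilated, radius_mm, spacing)


def deform_target(
    current: np.ndarray,
    regions: HotColdRegions,
    params: DMDParams,
    itv: np.ndarray,
    body: np.ndarray,
    grid: ImageGrid,
) -> np.ndarray:
    """One morphological DMD update of the aperture-fitting target.

    Expansion adds only voxels within one step of the current surface that
    are adjacent to cold regions; shrinkage removes only surface-band
    voxels adjacent to hot regions; a closing of ``smooth_radius_mm``
    smooths the result, which is clipped to the body (and kept a superset
    of the ITV unless disabled).
    """
    current = np.asarray(current, dtype=bool)
    if not current.any():
        raise DMDError("target collapsed")
    spacing = grid.spacing
    step = params.step_mm if params.step_mm is not None else float(max(spacing))

    grow = _dilate(regions.cold, step, spacing) & _dilate(current, step, spacing)
    inner = ndimage.distance_transform_edt(current, sampling=spacing)
    surface_band = current & (inner <= step)
    shrink = _dilate(regions.hot, step, spacing) & surface_band

    new = (current | grow) & ~shrink
    new = _close(new, params.smooth_radius_mm, spacing)
    if params.require_itv:
        new |= np.asarray(itv, dtype=bool)
    new &= np.asarray(body, dtype=bool)
    if not new.any():
        raise DMDError("target collapsed")
    return new


@dataclass
class IterationRecord:
    """One accepted round of the loop (iteration 0 = conventional DCA)."""

    iteration: int
    metrics: PlanMetrics
    hot_cc: float
    cold_cc: float
    scale: float
    rx_isodose_level: float
    target_cc: float


@dataclass
class DMDResult:
    plan: Plan
    dose: DoseGrid  # Gy, best iteration
    history: list[IterationRecord]
    best_iteration: int
    target_mask: np.ndarray  # the PTV-DMD of the best iteration
    warning: str | None = None

    @property
    def baseline(self) -> IterationRecord:
        return self.history[0]

    @property
    def best(self) -> IterationRecord:
        return self.history[self.best_iteration]


def run_dmd(
    density: ImageGrid,
    structures: StructureSet,
    arc: ArcSpec,
    geometry: BeamGeometry,
    beam: BeamModel,
    params: DMDParams = DMDParams(),
    prescription: FractionationScheme | None = None,
    margin_mm: float = 0.0,
    bev_pitch_mm: float = 1.0,
    coverage_fraction: float = 0.95,
) -> DMDResult:
    """Full DMD loop: baseline DCA, then deform / re-plan / renormalize.

    Hot and cold regions are always evaluated against the ORIGINAL PTV, and
    every iteration is renormalized to 95 % coverage of the ORIGINAL PTV.
    Failures inside the loop (collapsed target, unattainable coverage)
    return the best previous iteration with a warning instead of raising.
    """
    structures.validate()
    ptv0 = structures["ptv"]
    itv = structures["itv"]
    body = structures["body"]
    grid = structures.grid
    if prescription is None:
        prescription = FractionationScheme(18.0, 3)
    rx = prescription.total_gy

    iso = mask_centroid(ptv0, grid)
    geometry = geometry.with_isocenter(iso)
    angles = make_arc(arc)
    engine = ArcDoseEngine(density, geometry, angles, beam, bev_pitch_mm=bev_pitch_mm)

    history: list[IterationRecord] = []
    plans: list[Plan] = []
    doses: list[DoseGrid] = []
    targets: list[np.ndarray] = []
    warning: str | None = None

    target = ptv0.copy()
    regions: HotColdRegions | None = None
    for it in range(params.max_iters + 1):
        if it > 0:
            assert regions is not None
            if regions.hot_cc <= params.stop_tol_cc and regions.cold_cc <= params.stop_tol_cc:
                break
            try:
                target = deform_target(target, regions, params, itv, body, grid)
            except DMDError as exc:
                warning = f"iteration {it}: {exc}"
                break
        apertures = fit_arc_apertures(target, grid, geometry, angles, margin_mm, bev_pitch_mm)
        raw = engine.compute(apertures)
        try:
            norm = normalize_to_coverage(raw, ptv0, prescription, coverage_fraction)
        except PlanningError as exc:
            warning = f"iteration {it}: {exc}"
            break
        regions = find_hot_cold(norm.dose, ptv0, body, rx, grid)
        # Invariants by construction, asserted in-loop: hot never intersects
        # the PTV and cold never leaves it.
        assert not np.any(regions.hot & ptv0)
        assert not np.any(regions.cold & ~ptv0)
        metrics = evaluate_plan(norm.dose, structures, prescription)
        history.append(
            IterationRecord(
                iteration=it,
                metrics=metrics,
                hot_cc=regions.hot_cc,
                cold_cc=regions.cold_cc,
                scale=norm.scale,
                rx_isodose_level=norm.rx_isodose_level,
                target_cc=mask_volume_cc(target, grid),
            )
        )
        plans.append(
            Plan(arc, geometry, apertures,
                 "ptv" if it == 0 else "ptv_dmd",
                 prescription, norm.scale, bev_pitch_mm)
        )
        doses.append(norm.dose)
        targets.append(target.copy())

    if not history:
        raise DMDError(f"no iteration completed ({warning})")

    # Best conformity: CI closest to its ideal of 1; ties -> fewer rounds.
    ci_dev = [abs(rec.metrics.ci - 1.0) for rec in history]
    best = int(np.argmin(ci_dev))
    return DMDResult(
        plan=plans[best],
        dose=doses[best],
        history=history,
        best_iteration=best,
        target_mask=targets[best],
        warning=warning,
    )
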