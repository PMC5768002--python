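"""Dose engine closed forms, monotonicity, and arc symmetry."""

import dataclasses

import numpy as np
import pytest

from arcdmd import (
    ArcSpec,
    BeamGeometry,
    BeamModel,
    compute_cp_dose,
    compute_plan_dose,
    make_arc,
    plan_dca,
)
from arcdmd.dose_engine import ArcDoseEngine
from arcdmd.geometry import ControlPointAperture
from arcdmd.phantom import ImageGrid, StructureSet

from conftest import small_grid


def _open_field(geometry: BeamGeometry, half_mm: float = 80.0, gantry: float = 0.0):
    n = geometry.n_leaf_pairs
    return ControlPointAperture(
        gantry, np.full(n, -half_mm), np.full(n, half_mm), np.ones(n, dtype=bool)
    )


def water_grid(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0), density=1.0):
    g = small_grid(shape, spacing)
    return g.with_values(np.full(g.shape, density))


class TestCpDose:
    def test_central_axis_matches_closed_form(self):
        # Homogeneous water, wide open field: depth-dose ratio equals
        # exp(-mu (d2 - d1)) x inverse square, within 1 %.
        grid = water_grid()
        geo = BeamGeometry()
        beam = BeamModel()
        dose = compute_cp_dose(grid, _open_field(geo), geo, beam).values
        mid = grid.shape[0] // 2  # central axis: x = z = 0, beam along -y
        ys = grid.axes()[1]
        y_surface = ys[-1] + grid.spacing[1] / 2.0
        for j1, j2 in [(40, 30), (30, 12), (24, 6)]:
            got = dose[mid, j2, mid] / dose[mid, j1, mid]
            depth = ys[j1] - ys[j2]
            inv_sq = ((geo.sad_mm - ys[j1]) / (geo.sad_mm - ys[j2])) ** 2
            expected = np.exp(-beam.mu_eff_per_mm * depth) * inv_sq
            assert got == pytest.approx(expected, rel=0.01)
        # dose decreases with depth beyond the surface
        axis = dose[mid, :, mid]
        assert np.all(np.diff(axis) > 0)  # increasing y = decreasing depth

    def test_vacuum_dose_is_geometry_only(self):
        # Zero density: no attenuation; voxels equidistant from the source
        # with equal off-axis radius receive identical dose.
        grid = small_grid((17, 17, 17), (2.0, 2.0, 2.0)).with_values(
            np.zeros((17, 17, 17))
        )
        geo = BeamGeometry()
        beam = BeamModel(penumbra_sigma_mm=0.0)
        dose = compute_cp_dose(grid, _open_field(geo), geo, beam).values
        # gantry 0: beam along -y; +-x mirror voxels are equivalent
        assert np.allclose(dose[4, :, 8], dose[12, :, 8], rtol=1e-10)

    def test_closed_region_gets_zero_without_penumbra(self):
        grid = water_grid((32, 32, 32))
        geo = BeamGeometry()
        beam = BeamModel(penumbra_sigma_mm=0.0)
        n = geo.n_leaf_pairs
        # open only a narrow central slit; far-off-slit voxels get nothing
        ap = ControlPointAperture(
            0.0, np.full(n, -5.0), np.full(n, 5.0),
            np.abs(geo.leaf_centers()) <= 5.0,
        )
        dose = compute_cp_dose(grid, ap, geo, beam).values
        assert dose[16, 16, 16] > 0
        assert dose[16, 16, 30] == 0.0  # ~42 mm above slit: leaves closed
        assert dose[2, 16, 16] == 0.0  # ~42 mm lateral: outside slit


class TestPlanDose:
    def test_single_control_point_equals_cp_dose_times_scale(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        geo = BeamGeometry()
        beam = BeamModel()
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 340.0), geo,
                        prescription=spec.fractionation)
        assert len(plan.apertures) == 2
        plan1 = dataclasses.replace(plan, arc=ArcSpec(340.0, 340.0),
                                    apertures=plan.apertures,
                                    normalization_scale=3.0)
        d_plan = compute_plan_dose(grid, plan1, beam).values
        parts = [
            compute_cp_dose(grid, ap, plan.geometry, beam).values
            for ap in plan.apertures
        ]
        assert np.allclose(d_plan, 3.0 * (parts[0] + parts[1]), rtol=1e-12)

    def test_dose_linear_in_normalization(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 85.0), BeamGeometry(),
                        prescription=spec.fractionation)
        beam = BeamModel()
        d1 = compute_plan_dose(grid, plan, beam).values
        d2 = compute_plan_dose(grid, dataclasses.replace(plan, normalization_scale=2.5),
                               beam).values
        assert np.allclose(d2, 2.5 * d1, rtol=1e-12)

    def test_margin_enlargement_never_decreases_dose(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        arc = ArcSpec(340.0, 34.0)
        beam = BeamModel()
        p0 = plan_dca(structures, "ptv", arc, BeamGeometry(), margin_mm=0.0,
                      prescription=spec.fractionation)
        p2 = plan_dca(structures, "ptv", arc, BeamGeometry(), margin_mm=2.0,
                      prescription=spec.fractionation)
        d0 = compute_plan_dose(grid, p0, beam).values
        d2 = compute_plan_dose(grid, p2, beam).values
        assert np.all(d2 >= d0 - 1e-12)

    def test_denser_phantom_never_increases_dose(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        arc = ArcSpec(340.0, 85.0)
        beam = BeamModel()
        plan = plan_dca(structures, "ptv", arc, BeamGeometry(),
                        prescription=spec.fractionation)
        d1 = compute_plan_dose(grid, plan, beam).values
        denser = grid.with_values(grid.values * 1.1)
        d2 = compute_plan_dose(denser, plan, beam).values
        assert np.all(d2 <= d1 + 1e-12)

    def test_full_arc_rotational_symmetry(self):
        # Cylindrical water phantom, 360 deg arc, spherical target: dose is
        # axially symmetric (RMS deviation from the rotational mean < 2 % of max).
        grid = small_grid((48, 48, 48), (3.0, 3.0, 3.0))
        gx, gy, gz = grid.meshgrid()
        rad = np.hypot(gx, gy)
        body = rad <= 66.0
        density = np.where(body, 1.0, 0.0)
        grid = grid.with_values(density)
        target = (gx**2 + gy**2 + gz**2) <= 12.0**2
        structures = StructureSet(grid, {"body": body, "lung_left": body & False,
                                         "lung_right": body & False, "itv": target,
                                         "ptv": target})
        plan = plan_dca(structures, "ptv", ArcSpec(360.0, 10.0), BeamGeometry())
        dose = compute_plan_dose(grid, plan, BeamModel()).values
        sel = body & (rad <= 60.0)
        rbin = np.round(rad / 3.0).astype(int)
        mean_map = np.zeros_like(dose)
        for z in range(48):
            sums = np.bincount(rbin[:, :, z][sel[:, :, z]],
                               weights=dose[:, :, z][sel[:, :, z]])
            counts = np.bincount(rbin[:, :, z][sel[:, :, z]])
            with np.errstate(invalid="ignore"):
                avg = sums / counts
            mean_map[:, :, z][sel[:, :, z]] = avg[rbin[:, :, z][sel[:, :, z]]]
        rms = np.sqrt(np.mean((dose[sel] - mean_map[sel]) ** 2))
        assert rms < 0.02 * dose.max()

    def test_control_point_density_convergence(self):
        # Halving the control-point spacing changes no voxel by more than
        # 1 % of the maximum dose.
        grid = water_grid((32, 32, 32), (4.0, 4.0, 4.0))
        gx, gy, gz = grid.meshgrid()
        target = (gx**2 + (gy / 1.5) ** 2 + gz**2) <= 14.0**2
        body = np.ones(grid.shape, dtype=bool)
        structures = StructureSet(grid, {"body": body, "lung_left": body & False,
                                         "lung_right": body & False, "itv": target,
                                         "ptv": target})
        beam = BeamModel()
        doses = {}
        for spacing in (4.0, 2.0):
            plan = plan_dca(structures, "ptv", ArcSpec(340.0, spacing), BeamGeometry())
            d = compute_plan_dose(grid, plan, beam).values
            doses[spacing] = d / len(plan.apertures)  # per-CP average
        diff = np.abs(doses[4.0] - doses[2.0]).max()
        assert diff < 0.01 * doses[2.0].max()

    def test_aperture_count_mismatch_rejected(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 85.0), BeamGeometry())
        engine = ArcDoseEngine(grid, plan.geometry, make_arc(plan.arc), BeamModel())
        with pytest.raises(Exception, match="apertures"):
            engine.compute(plan.apertures[:-1])
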