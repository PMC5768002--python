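"""DVH statistics, coverage normalization, and DCA plan construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcdmd import (
    ArcSpec,
    BeamGeometry,
    DoseGrid,
    PlanningError,
    compute_dvh,
    normalize_to_coverage,
    plan_dca,
)
from arcdmd.phantom import FractionationScheme, PhantomSpec, StructureSet, make_phantom
from arcdmd.phantom import params_for_volume

from _oracles import oracle_percentile_dx
from conftest import small_grid


class TestDVH:
    def test_uniform_dose(self):
        grid = small_grid((8, 8, 8))
        mask = np.zeros(grid.shape, bool)
        mask[2:6, 2:6, 2:6] = True
        dose = np.where(mask, 10.0, 3.0)
        dvh = compute_dvh(grid.with_values(dose), mask)
        for stat in (dvh.d2, dvh.d50, dvh.d98, dvh.dmax, dvh.dmean):
            assert stat == pytest.approx(10.0)
        assert dvh.vx(9.99) == 1.0
        assert dvh.vx(10.01) == 0.0

    def test_two_voxel_mask(self):
        grid = small_grid((8, 8, 8))
        mask = np.zeros(grid.shape, bool)
        mask[1, 1, 1] = mask[6, 6, 6] = True
        dose = np.zeros(grid.shape)
        dose[1, 1, 1], dose[6, 6, 6] = 8.0, 12.0
        dvh = compute_dvh(grid.with_values(dose), mask)
        assert dvh.dmean == pytest.approx(10.0)
        assert dvh.dmax == 12.0
        assert dvh.vx(10.0) == 0.5

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(11)
        grid = small_grid((20, 20, 20))
        dose = rng.gamma(3.0, 10.0, size=grid.shape)
        mask = rng.random(grid.shape) < 0.3
        dvh = compute_dvh(grid.with_values(dose), mask)
        sample = dose[mask]
        bin_width = max(0.1, sample.max() / 2000)
        for x in (2.0, 50.0, 98.0):
            assert abs(dvh.dx(x) - oracle_percentile_dx(sample, x)) <= bin_width

    def test_curve_is_cumulative(self):
        rng = np.random.default_rng(2)
        grid = small_grid((12, 12, 12))
        dose = rng.exponential(20.0, size=grid.shape)
        mask = rng.random(grid.shape) < 0.5
        dvh = compute_dvh(grid.with_values(dose), mask)
        assert dvh.cum_volume[0] == 1.0
        assert np.all(np.diff(dvh.cum_volume) <= 1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_stat_ordering_invariants(self, seed):
        rng = np.random.default_rng(seed)
        grid = small_grid((10, 10, 10))
        dose = rng.gamma(2.0, 15.0, size=grid.shape)
        mask = rng.random(grid.shape) < 0.4
        mask[5, 5, 5] = True
        dvh = compute_dvh(grid.with_values(dose), mask)
        assert dvh.d2 >= dvh.d50 >= dvh.d98
        assert dvh.dmax >= dvh.d2
        assert dvh.dmax >= dvh.dmean

    def test_empty_mask_rejected(self):
        grid = small_grid((8, 8, 8))
        with pytest.raises(PlanningError, match="empty"):
            compute_dvh(grid.with_values(np.ones(grid.shape)), np.zeros(grid.shape, bool))


class TestNormalization:
    def test_uniform_dose_scales_to_rx_exactly(self):
        grid = small_grid((10, 10, 10))
        mask = np.zeros(grid.shape, bool)
        mask[3:7, 3:7, 3:7] = True
        dose = DoseGrid(grid.with_values(np.where(mask, 20.0, 5.0)))
        res = normalize_to_coverage(dose, mask, 54.0)
        assert res.scale == pytest.approx(54.0 / 20.0)
        assert np.all(res.dose.values[mask] >= 54.0 - 1e-9)  # 100 % coverage

    def test_coverage_fraction_in_band(self):
        rng = np.random.default_rng(5)
        grid = small_grid((16, 16, 16))
        mask = rng.random(grid.shape) < 0.4
        dose = DoseGrid(grid.with_values(rng.gamma(5.0, 4.0, size=grid.shape) + 0.1))
        res = normalize_to_coverage(dose, mask, 55.0)
        n = np.count_nonzero(mask)
        frac = np.count_nonzero(res.dose.values[mask] >= 55.0) / n
        assert 0.95 <= frac <= 0.95 + 1.0 / n

    def test_linearity(self):
        rng = np.random.default_rng(8)
        grid = small_grid((12, 12, 12))
        mask = rng.random(grid.shape) < 0.5
        base = rng.gamma(5.0, 4.0, size=grid.shape) + 0.1
        r1 = normalize_to_coverage(DoseGrid(grid.with_values(base)), mask, 54.0)
        r2 = normalize_to_coverage(DoseGrid(grid.with_values(2.0 * base)), mask, 54.0)
        assert r2.scale == pytest.approx(r1.scale / 2.0, rel=1e-12)
        assert np.allclose(r1.dose.values, r2.dose.values, rtol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        grid = small_grid((12, 12, 12))
        mask = rng.random(grid.shape) < 0.5
        dose = DoseGrid(grid.with_values(rng.gamma(5.0, 4.0, size=grid.shape) + 0.1))
        once = normalize_to_coverage(dose, mask, 54.0)
        twice = normalize_to_coverage(once.dose, mask, 54.0)
        assert twice.scale == pytest.approx(1.0, abs=1e-9)

    def test_rx_isodose_level_definition(self):
        grid = small_grid((10, 10, 10))
        mask = np.zeros(grid.shape, bool)
        mask[4:6, 4:6, 4:6] = True
        vals = np.where(mask, 10.0, 1.0)
        vals[0, 0, 0] = 25.0  # global hot point
        res = normalize_to_coverage(DoseGrid(grid.with_values(vals)), mask, 50.0)
        assert res.rx_isodose_level == pytest.approx(50.0 / res.dose.values.max())

    def test_unattainable_coverage_rejected(self):
        grid = small_grid((10, 10, 10))
        mask = np.zeros(grid.shape, bool)
        mask[2:8, 2:8, 2:8] = True
        vals = np.where(mask, 1.0, 0.0)
        vals[mask] = np.where(np.arange(mask.sum()) < 0.9 * mask.sum(), 1.0, 0.0)
        with pytest.raises(PlanningError, match="coverage unattainable"):
            normalize_to_coverage(DoseGrid(grid.with_values(vals)), mask, 54.0)


class TestPlanDca:
    def test_sphere_apertures_identical_across_angles(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 68.0), BeamGeometry(),
                        prescription=spec.fractionation)
        ref = plan.apertures[0]
        # silhouettes agree up to voxelization (half a voxel diagonal) plus
        # one BEV pixel
        slack = float(np.linalg.norm(grid.spacing)) / 2.0 + plan.bev_pitch_mm
        for ap in plan.apertures[1:]:
            assert np.array_equal(ap.is_open, ref.is_open)
            assert np.allclose(ap.left_edges[ap.is_open], ref.left_edges[ref.is_open],
                               atol=slack)
            assert np.allclose(ap.right_edges[ap.is_open], ref.right_edges[ref.is_open],
                               atol=slack)

    def test_margin_pass_through(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        arc = ArcSpec(340.0, 85.0)
        p0 = plan_dca(structures, "ptv", arc, BeamGeometry(), margin_mm=0.0)
        p3 = plan_dca(structures, "ptv", arc, BeamGeometry(), margin_mm=3.0)
        for a0, a3 in zip(p0.apertures, p3.apertures):
            sel = a0.is_open
            assert np.allclose(a3.left_edges[sel], a0.left_edges[sel] - 3.0)
            assert np.allclose(a3.right_edges[sel], a0.right_edges[sel] + 3.0)

    def test_bilobed_target_closes_leaves_between_lobes(self):
        # Two lobes separated cranio-caudally by more than a leaf band:
        # every control point has a closed pair between the lobes' bands.
        spec = PhantomSpec.preset(
            "coarse", tumor_shape="bilobed",
            tumor_params={"r1": 9.0, "r2": 9.0, "sep": 40.0},
        )
        grid, structures = make_phantom(spec)
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 68.0), BeamGeometry())
        geo = plan.geometry
        centers = geo.leaf_centers()
        for ap in plan.apertures:
            # bands fully inside the gap between lobes (|z_bev| < 1.5 mm):
            gap_bands = np.abs(centers) <= 1.5
            assert not ap.is_open[gap_bands].any()
            assert ap.is_open.sum() >= 2  # both lobes open

    def test_isocenter_is_target_centroid(self, coarse_ellipsoid):
        spec, grid, structures = coarse_ellipsoid
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 170.0), BeamGeometry())
        from arcdmd.planning import mask_centroid

        assert np.allclose(plan.geometry.isocenter_mm,
                           mask_centroid(structures["ptv"], grid))

    def test_empty_target_rejected(self, coarse_sphere):
        spec, grid, structures = coarse_sphere
        s2 = StructureSet(grid, {**structures.masks,
                                 "empty": np.zeros(grid.shape, bool)})
        with pytest.raises(PlanningError, match="empty"):
            plan_dca(s2, "empty", ArcSpec(340.0, 85.0), BeamGeometry())

    def test_plan_json_roundtrip(self, tmp_path, coarse_sphere):
        spec, grid, structures = coarse_sphere
        plan = plan_dca(structures, "ptv", ArcSpec(340.0, 170.0), BeamGeometry(),
                        prescription=FractionationScheme(11.0, 5))
        plan.to_json(tmp_path / "plan.json")
        import json

        d = json.loads((tmp_path / "plan.json").read_text())
        assert d["prescription"]["n_fractions"] == 5
        assert len(d["apertures"]) == len(plan.apertures)
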