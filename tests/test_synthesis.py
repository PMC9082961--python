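"""Ground-truth geometry, population sampling, rendering and weighing sims."""

import math

import numpy as np
import pytest

from leafvol import optical, volumetry
from leafvol.synthesis import (LeafShapeParams, LeafSpecimen, PopulationParams,
                               lamina_volume, mean_thickness,
                               midrib_addon_volume, render_scan,
                               sample_population, sample_study_set,
                               simulate_sgb_weighing,
                               simulate_suspension_weighing, true_area,
                               true_volume)
from tests.conftest import make_shape


class TestTrueGeometry:
    def test_rectangle_closed_form(self, rectangle_specimen):
        assert true_area(rectangle_specimen) == pytest.approx(1000.0, rel=1e-8)

    def test_triangle_closed_form(self, triangle_specimen):
        assert true_area(triangle_specimen) == pytest.approx(500.0, rel=1e-8)

    def test_lanceolate_closed_form(self, lanceolate_specimen):
        # integral of sqrt(4u(1-u)) over [0,1] is pi/4
        expected = 150.0 * 10.0 * math.pi / 4.0
        assert true_area(lanceolate_specimen) == pytest.approx(expected, rel=1e-7)

    def test_area_additive_over_partition(self, lanceolate_specimen):
        shape = lanceolate_specimen.shape
        cuts = [0.0, 23.0, 77.5, 110.0, 150.0]
        pieces = [LeafSpecimen(shape=shape, piece_interval=(a, b))
                  for a, b in zip(cuts[:-1], cuts[1:])]
        total = sum(true_area(p) for p in pieces)
        assert total == pytest.approx(true_area(lanceolate_specimen), rel=1e-6)
        total_v = sum(true_volume(p, include_midrib=False) for p in pieces)
        assert total_v == pytest.approx(
            true_volume(lanceolate_specimen, include_midrib=False), rel=1e-6)

    def test_constant_thickness_slab_volume(self, rectangle_specimen):
        v = true_volume(rectangle_specimen, include_midrib=False)
        assert v == pytest.approx(1000.0 * 0.25, rel=1e-8)

    def test_midrib_addon_matches_solid_model(self, lanceolate_specimen):
        incl = true_volume(lanceolate_specimen, include_midrib=True)
        excl = true_volume(lanceolate_specimen, include_midrib=False)
        expected = volumetry.midrib_volume(150.0, 0.80, "cone")
        assert incl - excl == pytest.approx(expected, rel=1e-12)

    def test_piece_uses_cylinder_and_local_basal_diameter(self):
        spec = LeafSpecimen(shape=make_shape(), piece_interval=(75.0, 120.0))
        d_at_cut = spec.shape.midrib_diameter(75.0)
        expected = volumetry.midrib_volume(45.0, float(d_at_cut), "cylinder")
        assert midrib_addon_volume(spec) == pytest.approx(expected, rel=1e-12)

    def test_midrib_mismatch_scales_true_volume_only(self):
        base = LeafSpecimen(shape=make_shape(), specimen_id="a")
        warped = LeafSpecimen(shape=make_shape(), specimen_id="a",
                              midrib_mismatch=1.2)
        delta = true_volume(warped) - true_volume(base)
        assert delta == pytest.approx(0.2 * midrib_addon_volume(base), rel=1e-9)
        assert midrib_addon_volume(warped, apply_mismatch=False) == \
            midrib_addon_volume(base, apply_mismatch=False)

    def test_shape_invariants_rejected(self):
        with pytest.raises(ValueError):
            make_shape(thickness_base_mm=0.1, thickness_tip_mm=0.3)
        with pytest.raises(ValueError):
            make_shape(midrib_base_mm=0.1)
        with pytest.raises(ValueError):
            LeafSpecimen(shape=make_shape(), piece_interval=(50.0, 20.0))


class TestMeanThickness:
    def test_constant_thickness_exact(self, rectangle_specimen):
        for scheme in ("three_point", "every_2cm", "middle_only"):
            assert mean_thickness(rectangle_specimen, scheme) == \
                pytest.approx(0.25, abs=1e-12)

    def test_three_point_linear_taper(self):
        shape = make_shape(thickness_base_mm=0.30, thickness_middle_mm=0.25,
                           thickness_tip_mm=0.20)
        spec = LeafSpecimen(shape=shape)
        assert mean_thickness(spec, "three_point") == pytest.approx(0.25)

    def test_short_piece_gets_single_reading(self):
        shape = make_shape(length_mm=100.0, thickness_base_mm=0.30,
                           thickness_middle_mm=0.25, thickness_tip_mm=0.20)
        spec = LeafSpecimen(shape=shape, piece_interval=(0.0, 10.0))
        # the single reading sits mid-piece, at x = 5 mm
        expected = float(shape.lamina_thickness(5.0))
        assert mean_thickness(spec, "every_2cm") == pytest.approx(expected)

    def test_every_2cm_point_count(self):
        shape = make_shape(length_mm=100.0)
        spec = LeafSpecimen(shape=shape)
        # readings at 10, 30, 50, 70, 90 mm
        expected = float(np.mean(shape.lamina_thickness([10, 30, 50, 70, 90])))
        assert mean_thickness(spec, "every_2cm") == pytest.approx(expected)

    def test_unknown_scheme(self, rectangle_specimen):
        with pytest.raises(ValueError, match="scheme"):
            mean_thickness(rectangle_specimen, "random_walk")

    def test_reading_noise_is_seeded(self, rectangle_specimen):
        a = mean_thickness(rectangle_specimen, "three_point", noise_sd_mm=0.01,
                           rng=np.random.default_rng(7))
        b = mean_thickness(rectangle_specimen, "three_point", noise_sd_mm=0.01,
                           rng=np.random.default_rng(7))
        assert a == b != 0.25


class TestPopulationSampling:
    def test_zero_cv_gives_identical_specimens(self):
        params = PopulationParams(n=5, seed=1, cvs={})
        specs = sample_population(params)
        assert len(specs) == 5
        assert len({s.shape for s in specs}) == 1

    def test_same_seed_same_population(self):
        a = sample_population(PopulationParams(n=20, seed=42))
        b = sample_population(PopulationParams(n=20, seed=42))
        assert [s.shape for s in a] == [s.shape for s in b]

    def test_requested_cv_recovered_at_large_n(self):
        params = PopulationParams(n=1000, seed=9)
        specs = sample_population(params)
        t = np.array([s.shape.thickness_middle_mm for s in specs])
        cv = 100.0 * t.std(ddof=1) / t.mean()
        assert 10.2 <= cv <= 13.8  # 12% requested, +/-15% relative

    def test_all_dimension_cvs_within_tolerance(self):
        params = PopulationParams(n=1000, seed=3)
        specs = sample_population(params)
        dims = {
            "length": [s.shape.length_mm for s in specs],
            "width": [s.shape.max_width_mm for s in specs],
            "thickness_middle": [s.shape.thickness_middle_mm for s in specs],
        }
        for name, vals in dims.items():
            vals = np.asarray(vals)
            cv = vals.std(ddof=1) / vals.mean()
            target = params.cvs[name]
            assert abs(cv - target) <= 0.15 * target, name

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PopulationParams(n=0, seed=1)
        with pytest.raises(ValueError):
            PopulationParams(n=5, seed=1, means={"length": -3.0})

    def test_study_set_spans_area_range_with_midrib_share(self):
        specs = sample_study_set(14, seed=11)
        areas = np.array([true_area(s) for s in specs])
        assert areas.min() < 150 and areas.max() > 2000
        assert len({s.specimen_id for s in specs}) == 14
        frac = np.array([midrib_addon_volume(s, apply_mismatch=False)
                         / true_volume(s) for s in specs])
        assert (frac > 0.01).all() and (frac < 0.12).all()


class TestRenderScan:
    def test_square_inch_pixel_count(self):
        shape = make_shape(length_mm=25.4, max_width_mm=25.4,
                           width_mode="rectangular")
        spec = LeafSpecimen(shape=shape, specimen_id="sq")
        img = render_scan(spec, 200, rotation_deg=0.0, offset_px=(0.0, 0.0))
        assert img.pixel_count == 200 * 200

    def test_high_dpi_area_matches_quadrature(self):
        shape = make_shape(length_mm=150.0, max_width_mm=1000.0 / (math.pi / 4) / 150.0)
        spec = LeafSpecimen(shape=shape, specimen_id="x")
        img = render_scan(spec, 1200, seed=0)
        ola = optical.pixels_to_area(img.pixel_count, 1200)
        assert ola == pytest.approx(true_area(spec), rel=0.005)

    def test_render_deterministic_per_seed(self, lanceolate_specimen):
        a = render_scan(lanceolate_specimen, 300, seed=5)
        b = render_scan(lanceolate_specimen, 300, seed=5)
        assert a.pixel_count == b.pixel_count
        assert np.array_equal(a.mask, b.mask)

    def test_area_error_decreases_with_dpi(self, rng):
        shape = make_shape(length_mm=80.0, max_width_mm=300.0 / (math.pi / 4) / 80.0)
        spec = LeafSpecimen(shape=shape, specimen_id="s")
        a_true = true_area(spec)
        mean_err = {}
        for dpi in (200, 600, 1200):
            errs = [abs(optical.pixels_to_area(
                render_scan(spec, dpi, rng=rng).pixel_count, dpi) - a_true)
                for _ in range(50)]
            mean_err[dpi] = np.mean(errs)
        assert mean_err[200] > mean_err[600] > mean_err[1200]

    def test_oversized_specimen_rejected(self):
        shape = make_shape(length_mm=280.0, max_width_mm=20.0)
        spec = LeafSpecimen(shape=shape)
        with pytest.raises(ValueError, match="canvas"):
            render_scan(spec, 300, seed=0, canvas_mm=(100.0, 100.0))

    def test_dpi_bounds(self, rectangle_specimen):
        with pytest.raises(ValueError):
            render_scan(rectangle_specimen, 10, seed=0)


class TestWeighingSimulation:
    def test_suspension_prerounding_reading(self):
        rec = simulate_suspension_weighing(
            1000.0, 22.0, seed=0, resolution_g=0.0, n_replicates=1,
            retainer_volume_mm3=2000.0)[0]
        rho = volumetry.water_density(22.0)
        assert rec.dw_t - rec.dw_r == pytest.approx(1000.0 * rho, abs=1e-12)
        assert rec.dw_t - rec.dw_r == pytest.approx(0.998, abs=1e-3)

    def test_suspension_round_trip_within_rounding_bound(self):
        rho = volumetry.water_density(22.0)
        for v in (50.0, 800.0, 2500.0):
            recs = simulate_suspension_weighing(
                v, 22.0, seed=2, n_replicates=1, retainer_volume_mm3=2000.0)
            got, _ = volumetry.leaf_volume_suspension(recs, 2000.0)
            assert abs(got - v) <= 0.0005 / rho + 1e-9

    def test_noise_seeding(self):
        a = simulate_suspension_weighing(500.0, 22.0, seed=1, noise_sd_g=0.002,
                                         n_replicates=2)
        b = simulate_suspension_weighing(500.0, 22.0, seed=2, noise_sd_g=0.002,
                                         n_replicates=2)
        c = simulate_suspension_weighing(500.0, 22.0, seed=1, noise_sd_g=0.0,
                                         n_replicates=2)
        d = simulate_suspension_weighing(500.0, 22.0, seed=2, noise_sd_g=0.0,
                                         n_replicates=2)
        assert [r.dw_t for r in a] != [r.dw_t for r in b]
        assert [r.dw_t for r in c] == [r.dw_t for r in d]

    def test_sgb_zero_noise_inverse(self):
        rec = simulate_sgb_weighing(500.0, 0.45, 22.0, seed=0,
                                    resolution_g=0.0, n_replicates=1)[0]
        got, _ = volumetry.leaf_volume_sgb(rec, 2000.0)
        assert got == pytest.approx(500.0, abs=1e-9)

    def test_sgb_neutrally_buoyant_identity(self):
        rho = volumetry.water_density(22.0)
        rec = simulate_sgb_weighing(600.0, 600.0 * rho, 22.0, seed=0,
                                    resolution_g=0.0, n_replicates=1,
                                    record_w_r2=True, retainer_w_r1_g=20.0,
                                    retainer_volume_mm3=2000.0)[0]
        assert rec.w_t2 == pytest.approx(20.0 - 2000.0 * rho, abs=1e-9)
        assert rec.w_t2 == pytest.approx(rec.w_r2, abs=1e-9)

    def test_temperature_out_of_table_range(self):
        with pytest.raises(ValueError):
            simulate_suspension_weighing(100.0, 40.0, seed=0)
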