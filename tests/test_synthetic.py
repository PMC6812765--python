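"""Scene generator: lattice geometry, adsorption algebra, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import evnanoarray as ev
from evnanoarray.synthetic import DistSpec, constant, normal, uniform

from conftest import render_single_dome


class TestLayout:
    def test_exact_lattice_count(self):
        lay = ev.make_layout(ev.LayoutSpec(10_000, 10_000, pitch_nm=1000), seed=1)
        assert len(lay) == 100

    def test_millimetre_field_count_matches_floor_oracle(self):
        lay = ev.make_layout(ev.LayoutSpec(1e6, 1e6, pitch_nm=1200), seed=1)
        per_side = int(1e6 // 1200)
        assert per_side == 833
        assert len(lay) == per_side ** 2 == 693_889

    def test_chip_density_at_default_pitch(self):
        # pitch 1414.2 nm reproduces the chip's 5.0e5 spots/mm^2
        spec = ev.LayoutSpec(1e4, 1e4, pitch_nm=1414.2)
        assert spec.density_per_mm2 == pytest.approx(5.0e5, rel=1e-3)

    @pytest.mark.parametrize("pitch", [250.0, 400.0, 1000.0, 1414.2, 2000.0])
    def test_density_law(self, pitch):
        spec = ev.LayoutSpec(2e4, 2e4, pitch_nm=pitch)
        assert spec.density_per_mm2 == pytest.approx((1e6 / pitch) ** 2, rel=1e-9)

    def test_field_smaller_than_pitch_errors(self):
        with pytest.raises(ValueError, match="empty layout"):
            ev.make_layout(ev.LayoutSpec(500, 500, pitch_nm=1000), seed=0)

    def test_brush_heights_within_bounds_and_deterministic(self):
        spec = ev.LayoutSpec(5000, 5000, pitch_nm=500)
        a = ev.make_layout(spec, seed=42)
        b = ev.make_layout(spec, seed=42)
        assert np.array_equal(a.brush_height_nm, b.brush_height_nm)
        assert np.all((a.brush_height_nm >= 2.0) & (a.brush_height_nm <= 3.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ev.LayoutSpec(1000, 1000, pitch_nm=100, spot_diameter_nm=200)


class TestPopulation:
    def test_adsorption_geometry_example(self):
        p = ev.TrueParticle.from_suspension(27.7, 0.20)
        assert p.d_true_nm == pytest.approx(47.4, abs=0.05)
        assert p.h_true_nm == pytest.approx(9.5, abs=0.05)
        # volume conservation cross-check: D^3 = d^2 h
        assert p.d_true_nm ** 2 * p.h_true_nm == pytest.approx(27.7 ** 3, rel=1e-12)

    def test_undeformed_sphere_limit(self):
        p = ev.TrueParticle.from_suspension(30.0, 1.0)
        assert p.d_true_nm == pytest.approx(30.0, rel=1e-12)
        assert p.h_true_nm == pytest.approx(30.0, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(D=st.floats(5.0, 300.0), ar=st.floats(0.01, 1.0))
    def test_volume_and_ratio_identities(self, D, ar):
        p = ev.TrueParticle.from_suspension(D, ar)
        assert p.h_true_nm / p.d_true_nm == pytest.approx(ar, rel=1e-9)
        assert p.D_true_nm ** 3 == pytest.approx(p.d_true_nm ** 2 * p.h_true_nm, rel=1e-9)

    def test_sampled_population_respects_identities(self):
        pop = ev.sample_population(50, normal(27.7, 4.7, low=0.0),
                                   normal(0.2, 0.04, low=0.0, high=1.0), seed=3)
        assert len(pop) == 50
        for p in pop:
            assert 0 < p.ar_true <= 1
            assert p.h_true_nm / p.d_true_nm == pytest.approx(p.ar_true, rel=1e-9)

    def test_reproducible_given_seed(self):
        kw = dict(D_dist=normal(27.7, 4.7), ar_dist=normal(0.2, 0.04, 0.0, 1.0))
        a = ev.sample_population(20, seed=9, **kw)
        b = ev.sample_population(20, seed=9, **kw)
        assert [p.D_true_nm for p in a] == [p.D_true_nm for p in b]

    def test_unsatisfiable_distribution_errors(self):
        with pytest.raises(ValueError, match="cannot produce"):
            ev.sample_population(5, constant(-1.0), uniform(0.1, 0.3), seed=0)
        with pytest.raises(ValueError, match="cannot produce"):
            ev.sample_population(5, constant(30.0), constant(1.5), seed=0)


class TestRender:
    def test_flat_brush_disc_max(self, single_spot_layout):
        cfg = ev.RenderConfig(pixel_size_nm=5, noise_sd_nm=0, seed=0)
        hmap, _ = ev.render_scene(single_spot_layout, [], cfg)
        assert hmap.heights.max() == pytest.approx(2.5, abs=1e-12)
        assert hmap.heights.min() == 0.0

    def test_dome_apex_height(self, bare_layout):
        hmap, _, p = render_single_dome(bare_layout, d=60, ar=0.2, pixel=2)
        # apex within half-pixel discretization of the analytic 12 nm
        assert hmap.heights.max() == pytest.approx(12.0, abs=0.05)

    def test_dome_on_brush_is_raised_by_brush(self, single_spot_layout):
        hmap, _, p = render_single_dome(single_spot_layout, d=60, ar=0.2, pixel=2)
        assert hmap.heights.max() == pytest.approx(12.0 + 2.5, abs=0.05)

    def test_prenoise_field_bit_identical_across_runs(self, single_spot_layout):
        a, _, _ = render_single_dome(single_spot_layout, noise=0.0, seed=5)
        b, _, _ = render_single_dome(single_spot_layout, noise=0.0, seed=5)
        assert np.array_equal(a.heights, b.heights)

    def test_noisy_field_deterministic_given_seed(self, single_spot_layout):
        a, _, _ = render_single_dome(single_spot_layout, noise=0.3, seed=5)
        b, _, _ = render_single_dome(single_spot_layout, noise=0.3, seed=5)
        assert np.array_equal(a.heights, b.heights)

    def test_under_resolved_warning(self, bare_layout):
        with pytest.warns(UserWarning, match="under-resolve"):
            render_single_dome(bare_layout, d=15, ar=0.4, pixel=5)

    def test_particle_outside_field_rejected(self, bare_layout):
        p = ev.TrueParticle.from_footprint(40, 0.2, 5000.0, 500.0)
        with pytest.raises(ValueError, match="outside the field"):
            ev.render_scene(bare_layout, [p], ev.RenderConfig(noise_sd_nm=0))


class TestTipBroadening:
    def test_dilation_is_extensive_and_monotone(self, bare_layout):
        h0, _, _ = render_single_dome(bare_layout, pixel=2, tip=0)
        h5, _, _ = render_single_dome(bare_layout, pixel=2, tip=5)
        h10, _, _ = render_single_dome(bare_layout, pixel=2, tip=10)
        assert np.all(h5.heights >= h0.heights - 1e-12)
        assert np.all(h10.heights >= h5.heights - 1e-12)

    def test_footprint_widens_apex_unchanged(self, bare_layout):
        h0, _, _ = render_single_dome(bare_layout, pixel=2, tip=0)
        h10, _, _ = render_single_dome(bare_layout, pixel=2, tip=10)
        assert h10.heights.max() == pytest.approx(h0.heights.max(), abs=1e-9)
        assert (h10.heights > 1.0).sum() > (h0.heights > 1.0).sum()

    def test_matches_brute_force_structuring_sweep(self, bare_layout):
        h0, _, _ = render_single_dome(bare_layout, pixel=4, tip=0)
        h8, _, _ = render_single_dome(bare_layout, pixel=4, tip=8)
        from evnanoarray.synthetic import _tip_structure

        fp, struct = _tip_structure(8.0, 4.0)
        r = fp.shape[0] // 2
        z = h0.heights
        # brute-force max over the structuring element at sample pixels
        for (i, j) in [(125, 125), (120, 130), (131, 126), (100, 100)]:
            best = -np.inf
            for du in range(-r, r + 1):
                for dv in range(-r, r + 1):
                    if fp[du + r, dv + r]:
                        best = max(best, z[i + du, j + dv] + struct[du + r, dv + r])
            assert h8.heights[i, j] == pytest.approx(best, abs=1e-9)


class TestSimulateScene:
    def test_truth_table_consistent_and_occupancy_exact(self):
        spec = ev.LayoutSpec(20 * 400, 10 * 400, pitch_nm=400, spot_diameter_nm=200)
        cfg = ev.RenderConfig(pixel_size_nm=5, noise_sd_nm=0.2, seed=0)
        hmap, truth, layout = ev.simulate_scene(
            spec, cfg, occupancy=0.2,
            D_dist=uniform(27, 35), ar_dist=uniform(0.18, 0.25), seed=11)
        assert len(layout) == 200
        assert truth.occupancy() == pytest.approx(0.20, abs=1e-12)
        truth.validate(layout)

    def test_truth_csv_roundtrip_columns(self, tmp_path):
        import evnanoarray.io as evio

        spec = ev.LayoutSpec(4 * 400, 4 * 400, pitch_nm=400)
        cfg = ev.RenderConfig(pixel_size_nm=5, noise_sd_nm=0.2, seed=0)
        _, truth, layout = ev.simulate_scene(spec, cfg, occupancy=0.5, seed=2)
        path = evio.write_truth_csv(truth, tmp_path / "truth.csv")
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns) == ["particle_id", "x_nm", "y_nm", "D_true_nm",
                                       "d_true_nm", "h_true_nm", "ar_true", "class",
                                       "spot_id"]
        assert (frame["class"] == "EV").sum() == len(truth.particles)
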