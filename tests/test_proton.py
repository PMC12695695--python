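import numpy as np
import pytest

from dualsct import proton
from dualsct.grid import VolumeGrid
from tests import oracles


@pytest.fixture(scope="module")
def water_volume():
    """Uniform water (HU 0): SPR exactly 1 everywhere; 1 mm voxels."""
    vol = VolumeGrid(np.zeros((200, 100, 100)), spacing_mm=(1, 1, 1),
                     origin_mm=(-100, -50, -50))
    return proton.hu_to_spr(vol)


@pytest.fixture(scope="module")
def beam():
    return proton.BeamSpec(direction=(1, 0, 0), field_size_mm=80.0,
                           r80_water_mm=120.0)


class TestSprCurve:
    def test_water_anchor(self):
        curve = proton.default_spr_curve()
        assert curve(np.array([0.0]))[0] == pytest.approx(1.0, abs=1e-3)

    def test_air_value(self):
        curve = proton.default_spr_curve()
        assert curve(np.array([-1024.0]))[0] == pytest.approx(0.001, abs=1e-6)

    def test_midpoint_linearity(self):
        curve = proton.SprCurve(((-1000, 0.0), (0, 1.0), (1000, 1.5)))
        hu = np.array([-500.0, 500.0])
        np.testing.assert_allclose(curve(hu), [0.5, 1.25])

    def test_out_of_range_clamps(self):
        curve = proton.default_spr_curve()
        assert curve(np.array([-5000.0]))[0] == curve(np.array([-1024.0]))[0]
        assert curve(np.array([9000.0]))[0] == curve(np.array([3072.0]))[0]

    def test_malformed_curves_rejected(self):
        with pytest.raises(ValueError):
            proton.SprCurve(((0, 1.0), (0, 1.1)))           # non-increasing HU
        with pytest.raises(ValueError):
            proton.SprCurve(((-100, 0.9), (0, 1.0), (100, 0.5)))  # SPR decreases
        with pytest.raises(ValueError):
            proton.SprCurve(((-100, 0.5), (100, 0.6)))      # violates water anchor

    def test_csv_round_trip(self, tmp_path):
        curve = proton.default_spr_curve()
        curve.to_csv(tmp_path / "c.csv")
        back = proton.SprCurve.from_csv(tmp_path / "c.csv")
        np.testing.assert_allclose(back.hu, curve.hu)
        np.testing.assert_allclose(back.spr, curve.spr)


class TestSprRelativeError:
    def test_identical_volumes_zero(self, rng):
        vol = VolumeGrid(rng.uniform(-500, 1500, size=(8, 8, 8)))
        pct, _ = proton.spr_relative_error(vol, vol)
        assert pct == 0.0

    def test_uniform_scale_on_linear_segment(self):
        # on the segment (0,1.0)-(60,1.04): HU 30 -> 1.02, HU 0 -> 1.0
        ct = VolumeGrid(np.zeros((5, 5, 5)))
        sct = VolumeGrid(np.full((5, 5, 5), 30.0))
        curve = proton.default_spr_curve()
        pct, _ = proton.spr_relative_error(sct, ct, curve)
        assert pct == pytest.approx(2.0, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        curve = proton.default_spr_curve()
        a = VolumeGrid(rng.uniform(-200, 1500, size=(6, 6, 6)))
        b = VolumeGrid(rng.uniform(-200, 1500, size=(6, 6, 6)))
        pct, _ = proton.spr_relative_error(a, b, curve)
        vals = []
        for idx in np.ndindex(a.shape):
            sa = float(curve(np.array([a.data[idx]]))[0])
            sb = float(curve(np.array([b.data[idx]]))[0])
            vals.append(abs(sa - sb) / sb * 100.0)
        assert pct == pytest.approx(np.mean(vals), rel=1e-9)

    def test_floor_mask_empty_rejected(self):
        air = VolumeGrid(np.full((4, 4, 4), -1024.0))
        with pytest.raises(ValueError):
            proton.spr_relative_error(air, air)


class TestWeplProfile:
    def test_uniform_water_linear(self, water_volume):
        d, w = proton.wepl_profile(water_volume, (-99.5, 0, 0), (1, 0, 0), 1.0)
        assert w[50] == pytest.approx(50.0, rel=1e-9)

    def test_slab_piecewise_sum(self):
        data = np.ones((40, 20, 20))
        data[:10] = 1.5  # 10 mm slab of SPR 1.5, then water
        vol = VolumeGrid(data, spacing_mm=(1, 1, 1), origin_mm=(0, -10, -10))
        d, w = proton.wepl_profile(vol, (-0.5, 0, 0), (1, 0, 0), 1.0,
                                   interpolation="nearest")
        assert w[30] == pytest.approx(35.0, rel=1e-9)

    def test_step_refinement_agrees(self, rng):
        data = 1.0 + 0.3 * rng.uniform(size=(60, 20, 20))
        vol = VolumeGrid(data, spacing_mm=(1, 1, 1), origin_mm=(0, -10, -10))
        _, coarse = proton.wepl_profile(vol, (-0.5, 0, 0), (1, 0, 0), 1.0)
        _, fine = proton.wepl_profile(vol, (-0.5, 0, 0), (1, 0, 0), 0.1)
        w_c = coarse[40]
        w_f = fine[400]
        assert abs(w_c - w_f) / w_f < 0.02

    def test_entry_outside_volume_rejected(self, water_volume):
        with pytest.raises(ValueError, match="outside"):
            proton.wepl_profile(water_volume, (500, 0, 0), (1, 0, 0), 1.0)

    def test_step_larger_than_voxel_rejected(self, water_volume):
        with pytest.raises(ValueError, match="step"):
            proton.wepl_profile(water_volume, (-99.5, 0, 0), (1, 0, 0), 2.0)


class TestBraggCurve:
    def test_distal_80_crossing_at_configured_range(self):
        w = np.arange(0.0, 200.0, 0.01)
        dose = proton.bragg_curve(w, 120.0)
        crossing = w[np.max(np.nonzero(dose >= 0.8))]
        assert crossing == pytest.approx(120.0, abs=0.011)

    def test_single_local_maximum(self):
        w = np.arange(0.0, 160.0, 0.01)
        dose = proton.bragg_curve(w, 100.0)
        diffs = np.sign(np.diff(dose))
        changes = np.sum(np.abs(np.diff(diffs[diffs != 0])) > 0)
        assert changes == 1  # rises then falls: one sign change

    def test_peak_before_range_and_normalized(self):
        w = np.arange(0.0, 200.0, 0.01)
        dose = proton.bragg_curve(w, 150.0)
        assert dose.max() == pytest.approx(1.0, abs=1e-6)
        assert w[dose.argmax()] < 150.0

    def test_doubling_range_doubles_crossing(self):
        w = np.arange(0.0, 300.0, 0.01)
        c1 = w[np.max(np.nonzero(proton.bragg_curve(w, 80.0) >= 0.8))]
        c2 = w[np.max(np.nonzero(proton.bragg_curve(w, 160.0) >= 0.8))]
        assert c2 == pytest.approx(2 * c1, abs=0.03)


class TestExtractDistalR80:
    def test_triangle_profile(self):
        depths = np.arange(0.0, 160.0, 1.0)
        dose = np.where(depths <= 100, depths / 100.0,
                        np.maximum(0.0, (150.0 - depths) / 50.0))
        line = proton.DoseLine(depths, dose)
        assert proton.extract_distal_r80(line) == pytest.approx(110.0, abs=1e-9)

    def test_plateau_never_below_80_rejected(self):
        depths = np.arange(0.0, 50.0, 1.0)
        line = proton.DoseLine(depths, np.full_like(depths, 0.9))
        with pytest.raises(proton.InvalidLineError):
            proton.extract_distal_r80(line)

    def test_coarse_grid_close_to_fine_grid(self):
        fine_w = np.arange(0.0, 160.0, 0.01)
        fine = proton.bragg_curve(fine_w, 110.0)
        fine_cross = fine_w[np.max(np.nonzero(fine >= 0.8))]
        coarse_w = np.arange(0.0, 160.0, 1.0)
        coarse = proton.bragg_curve(coarse_w, 110.0)
        got = proton.extract_distal_r80(proton.DoseLine(coarse_w, coarse / coarse.max()))
        assert abs(got - fine_cross) < 0.2


class TestDoseLinesAndR80Map:
    def test_water_identity(self, water_volume, beam):
        r80map = proton.compute_r80_map(water_volume, beam)
        vals = r80map.r80_mm[r80map.valid]
        assert r80map.valid.all()
        assert np.all(np.abs(vals - 120.0) < 1.0)

    def test_uniform_spr_scaling(self, water_volume, beam):
        for s in (0.8, 1.25):
            scaled = water_volume.with_data(np.full(water_volume.shape, s))
            m = proton.compute_r80_map(scaled, beam)
            vals = m.r80_mm[m.valid]
            assert np.all(np.abs(vals - 120.0 / s) < 1.0)

    def test_bone_slab_shortens_range(self, water_volume, beam):
        data = water_volume.data.copy()
        data[20:40] = 1.5  # 20 mm slab of SPR 1.5 upstream of the peak
        vol = water_volume.with_data(data)
        m = proton.compute_r80_map(vol, beam)
        vals = m.r80_mm[m.valid]
        # shallower than water by slab thickness x (SPR - 1) = 10 mm
        assert np.all(np.abs(vals - (120.0 - 10.0)) < 1.0)

    def test_mirrored_phantom_mirrors_map(self, beam):
        # volume symmetric about y = 0 (odd voxel count, centred grid):
        # the lateral R80 map must equal its own mirror
        rng = np.random.default_rng(0)
        data = 1.0 + 0.2 * rng.uniform(size=(200, 101, 101))
        data = 0.5 * (data + data[:, ::-1, :])
        vol = VolumeGrid(data, spacing_mm=(1, 1, 1), origin_mm=(-100, -50, -50))
        m = proton.compute_r80_map(vol, beam)
        np.testing.assert_allclose(m.r80_mm, m.r80_mm[::-1, :], atol=1e-6)

    def test_map_matches_per_line_calls(self, water_volume, beam):
        data = water_volume.data + 0.1 * np.sin(
            np.arange(water_volume.shape[1]) / 7.0)[None, :, None]
        vol = water_volume.with_data(data)
        m = proton.compute_r80_map(vol, beam)
        u, v = beam.lateral_axes()
        iso = np.asarray(beam.isocenter_mm, dtype=float)
        d = np.asarray(beam.direction)
        for iu in (0, 17, 80):
            for iv in (0, 40):
                offset_u, offset_v = m.u_mm[iu], m.v_mm[iv]
                entry = iso + offset_u * u + offset_v * v - 99.9999 * d
                line = proton.compute_dose_line(vol, entry, beam)
                r80 = proton.extract_distal_r80(line)
                assert r80 == pytest.approx(m.r80_mm[iu, iv], abs=0.02)

    def test_beam_missing_volume_rejected(self, water_volume):
        beam = proton.BeamSpec(direction=(1, 0, 0), isocenter_mm=(0, 500, 0),
                               field_size_mm=80.0, r80_water_mm=120.0)
        with pytest.raises(ValueError):
            proton.compute_r80_map(water_volume, beam)


class TestR80DifferenceHistogram:
    def _maps(self, base, shift):
        m1 = proton.R80Map(r80_mm=base, valid=np.ones_like(base, bool),
                           u_mm=np.arange(base.shape[0]),
                           v_mm=np.arange(base.shape[1]),
                           beam=proton.BeamSpec())
        m2 = proton.R80Map(r80_mm=base + shift, valid=np.ones_like(base, bool),
                           u_mm=m1.u_mm, v_mm=m1.v_mm, beam=m1.beam)
        return m1, m2

    def test_identical_maps_zero_errors(self, rng):
        base = rng.uniform(90, 110, size=(9, 9))
        m1, m2 = self._maps(base, 0.0)
        out = proton.r80_difference_histogram(m2, m1, 100.0)
        assert out["sd_pct"] == 0.0
        assert out["mean_pct"] == 0.0

    def test_one_mm_shift_is_one_percent(self, rng):
        base = rng.uniform(90, 110, size=(9, 9))
        m1, m2 = self._maps(base, 1.0)
        out = proton.r80_difference_histogram(m2, m1, 100.0)
        assert np.allclose(out["errors_pct"], 1.0)
        assert out["frac_within_1pct"] == 1.0

    def test_histogram_count_conserved(self, rng):
        base = rng.uniform(90, 110, size=(7, 7))
        m1, m2 = self._maps(base, rng.normal(0, 8, size=(7, 7)))
        out = proton.r80_difference_histogram(m2, m1, 100.0)
        assert out["counts"].sum() == out["n_beamlets"] == 49

    def test_disjoint_masks_rejected(self, rng):
        base = rng.uniform(90, 110, size=(4, 4))
        m1, m2 = self._maps(base, 0.0)
        m1.valid[:] = False
        with pytest.raises(ValueError):
            proton.r80_difference_histogram(m2, m1, 100.0)


class TestDvh:
    def test_uniform_dose_step_function(self):
        dose = np.full((5, 5, 5), 10.0)
        mask = np.ones((5, 5, 5), bool)
        curve = proton.compute_dvh(dose, mask, dose_bins=np.array([0, 5, 10, 15.0]))
        np.testing.assert_allclose(curve.volume_fraction, [1, 1, 1, 0])

    def test_half_half(self):
        dose = np.concatenate([np.full(50, 10.0), np.full(50, 20.0)]).reshape(4, 25, 1)
        mask = np.ones_like(dose, bool)
        curve = proton.compute_dvh(dose, mask, dose_bins=np.array([15.0]))
        assert curve.volume_fraction[0] == pytest.approx(0.5)

    def test_matches_sort_oracle(self, rng):
        dose = rng.uniform(0, 60, size=(6, 6, 6))
        mask = rng.uniform(size=(6, 6, 6)) < 0.5
        mask[3, 3, 3] = True
        bins = np.linspace(0, 70, 30)
        curve = proton.compute_dvh(dose, mask, dose_bins=bins)
        want = oracles.dvh_sort_oracle(dose[mask], bins)
        want[0] = 1.0
        np.testing.assert_allclose(curve.volume_fraction, want, atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        for _ in range(5):
            dose = rng.uniform(0, 100, size=(5, 5, 5))
            mask = np.ones((5, 5, 5), bool)
            curve = proton.compute_dvh(dose, mask)
            assert curve.volume_fraction[0] == 1.0
            assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
            assert np.all((curve.volume_fraction >= 0) & (curve.volume_fraction <= 1))
            assert curve.volume_fraction[-1] == 0.0

    def test_empty_structure_rejected(self, rng):
        with pytest.raises(ValueError):
            proton.compute_dvh(rng.uniform(0, 1, (3, 3, 3)), np.zeros((3, 3, 3), bool))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            proton.compute_dvh(np.full((2, 2, 2), -1.0), np.ones((2, 2, 2), bool))


class TestErrorPropagation:
    def test_soft_tissue_bias_shifts_range_systematically(self, beam):
        """A CBCT-like negative HU bias lowers SPR and pushes every R80
        deeper; an unbiased volume yields errors centred at zero."""
        rng = np.random.default_rng(5)
        hu = np.full((200, 100, 100), 30.0) + rng.normal(0, 5, (200, 100, 100))
        vol = VolumeGrid(hu, spacing_mm=(1, 1, 1), origin_mm=(-100, -50, -50))
        curve = proton.default_spr_curve()
        map_ref = proton.compute_r80_map(proton.hu_to_spr(vol, curve), beam)
        biased = vol.with_data(vol.data - 50.0)
        map_biased = proton.compute_r80_map(proton.hu_to_spr(biased, curve), beam)
        out = proton.r80_difference_histogram(map_biased, map_ref, beam.r80_water_mm)
        assert out["mean_pct"] > 0.5  # lower SPR -> deeper range, signed shift
        unbiased = vol.with_data(vol.data + rng.normal(0, 2, vol.shape))
        map_unb = proton.compute_r80_map(proton.hu_to_spr(unbiased, curve), beam)
        out0 = proton.r80_difference_histogram(map_unb, map_ref, beam.r80_water_mm)
        assert abs(out0["mean_pct"]) < 0.2
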