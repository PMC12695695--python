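import numpy as np
import pytest
from scipy import ndimage

from dualsct import metrics
from dualsct.grid import VolumeGrid
from dualsct.phantom import LabelVolume, VENTRICLE
from tests import oracles


@pytest.fixture()
def random_pairs(rng):
    """Random 9^3 volume pairs with random nonempty masks."""
    pairs = []
    for _ in range(20):
        a = rng.uniform(-1024, 3072, size=(9, 9, 9))
        b = a + rng.normal(0, 200, size=(9, 9, 9))
        mask = rng.uniform(size=(9, 9, 9)) < 0.5
        mask[4, 4, 4] = True  # never empty
        pairs.append((a, b, mask))
    return pairs


class TestMaskedMae:
    def test_identical_zero(self, rng):
        a = rng.normal(size=(5, 5, 5))
        m = np.ones((5, 5, 5), bool)
        assert metrics.masked_mae(a, a, m) == 0.0

    def test_constant_shift(self, rng):
        a = rng.normal(size=(5, 5, 5))
        m = rng.uniform(size=(5, 5, 5)) < 0.4
        m[0, 0, 0] = True
        assert metrics.masked_mae(a + 10.0, a, m) == pytest.approx(10.0, rel=1e-12)

    def test_matches_loop_oracle(self, random_pairs):
        for a, b, m in random_pairs:
            assert metrics.masked_mae(a, b, m) == pytest.approx(
                oracles.mae_loop(a, b, m), rel=1e-9)


class TestMaskedPsnr:
    def test_mse_equal_to_range_squared_gives_zero_db(self):
        a = np.zeros((3, 3, 3))
        b = np.full((3, 3, 3), 4096.0)
        m = np.ones((3, 3, 3), bool)
        assert metrics.masked_psnr(a, b, m) == pytest.approx(0.0, abs=1e-12)

    def test_identical_inputs_give_inf(self, rng):
        a = rng.normal(size=(4, 4, 4))
        assert metrics.masked_psnr(a, a, np.ones_like(a, bool)) == np.inf

    def test_empty_mask_rejected(self, rng):
        a = rng.normal(size=(3, 3, 3))
        with pytest.raises(ValueError):
            metrics.masked_psnr(a, a, np.zeros_like(a, bool))

    def test_matches_loop_oracle(self, random_pairs):
        for a, b, m in random_pairs:
            assert metrics.masked_psnr(a, b, m) == pytest.approx(
                oracles.psnr_loop(a, b, m, 4096.0), rel=1e-9)


class TestMaskedSsim:
    def test_identical_inputs_give_one(self, rng):
        a = rng.uniform(0, 4096, size=(9, 9, 9))
        m = np.ones((9, 9, 9), bool)
        assert metrics.masked_ssim(a, a, m) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_patch_nonpositive(self, rng):
        # zero-mean patch and its negation: covariance term is -variance, so
        # the local SSIM must be <= 0 where variance dominates the constants
        a = rng.normal(0, 2000, size=(9, 9, 9))
        a[1:8, 1:8, 1:8] -= a[1:8, 1:8, 1:8].mean()  # central 7^3 exactly zero-mean
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        assert metrics.masked_ssim(a, -a, m) <= 0.0

    def test_matches_sliding_window_oracle(self, random_pairs):
        for a, b, m in random_pairs[:8]:
            got = metrics.masked_ssim(a, b, m)
            want = oracles.ssim_loop(a, b, m, 7, 0.01, 0.03, 4096.0)
            assert got == pytest.approx(want, rel=1e-6)

    def test_mask_without_interior_rejected(self, rng):
        a = rng.normal(size=(9, 9, 9))
        m = np.zeros((9, 9, 9), bool)
        m[0, 0, 0] = True  # corner: window does not fit
        with pytest.raises(ValueError):
            metrics.masked_ssim(a, a, m)


class TestHuErrorMapAndHistogram:
    def _grids(self, data_a, data_b):
        return VolumeGrid(data_a), VolumeGrid(data_b)

    def test_identical_volumes_zero_map_and_central_mass(self, rng):
        a = rng.normal(size=(6, 6, 6))
        va, vb = self._grids(a, a.copy())
        assert np.all(metrics.hu_error_map(va, vb).data == 0)
        counts, edges = metrics.hu_difference_histogram(
            va, vb, np.ones((6, 6, 6), bool))
        zero_bin = np.searchsorted(edges, 0.0, side="right")  # +1 underflow offset
        assert counts[zero_bin] == 216

    def test_constant_shift_lands_in_one_bin(self, rng):
        a = rng.normal(size=(5, 5, 5))
        va, vb = self._grids(a + 100.0, a)
        counts, edges = metrics.hu_difference_histogram(
            va, vb, np.ones((5, 5, 5), bool))
        idx = np.searchsorted(edges, 100.0, side="right")  # overflow-shifted
        assert counts[idx] == 125

    def test_total_count_conserved(self, rng):
        a = rng.normal(0, 3000, size=(7, 7, 7))
        b = rng.normal(0, 3000, size=(7, 7, 7))
        mask = rng.uniform(size=(7, 7, 7)) < 0.3
        mask[0, 0, 0] = True
        counts, _ = metrics.hu_difference_histogram(
            VolumeGrid(a), VolumeGrid(b), mask)
        assert counts.sum() == mask.sum()


class TestDice:
    def test_identical_nonempty(self, rng):
        m = rng.uniform(size=(6, 6, 6)) < 0.4
        m[2, 2, 2] = True
        assert metrics.dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert metrics.dice_coefficient(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :4] = True
        b[0, 0, 2:4] = True
        b[0, 1, :2] = True
        assert metrics.dice_coefficient(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        e = np.zeros((3, 3, 3), bool)
        assert metrics.dice_coefficient(e, e) == 1.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            a = rng.uniform(size=(6, 6, 6)) < 0.3
            b = rng.uniform(size=(6, 6, 6)) < 0.3
            assert metrics.dice_coefficient(a, b) == pytest.approx(
                oracles.dice_loop(a, b), rel=1e-12)


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.uniform(size=(5, 5, 5)) < 0.4
        m[2, 2, 2] = True
        assert metrics.hausdorff_distance(m, m) == 0.0

    def test_two_voxels_on_2mm_grid(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 4, 4] = True
        b[6, 4, 4] = True
        assert metrics.hausdorff_distance(a, b, spacing=(2, 2, 2)) == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        n = m.copy()
        n[1, 1, 1] = True
        with pytest.raises(ValueError):
            metrics.hausdorff_distance(m, n)

    def test_matches_all_pairs_oracle(self, rng):
        spacing = (1.0, 2.0, 0.5)
        for _ in range(10):
            a = rng.uniform(size=(6, 6, 6)) < 0.2
            b = rng.uniform(size=(6, 6, 6)) < 0.2
            a[2, 2, 2] = b[3, 3, 3] = True
            got = metrics.hausdorff_distance(a, b, spacing)
            want = oracles.hausdorff_loop(a, b, spacing)
            assert got == pytest.approx(want, rel=1e-9)


class TestDelineationReport:
    def test_identical_labels_perfect_scores(self, label_volume):
        rep = metrics.delineation_report(label_volume, label_volume)
        present = rep[rep.present]
        assert (present.dsc == 1.0).all()
        assert (present.hd_mm == 0.0).all()

    def test_dilated_organ_detected(self, label_volume):
        data = label_volume.labels.data.copy()
        vent = data == VENTRICLE
        grown = ndimage.binary_dilation(vent, iterations=1)
        data[grown & (data != VENTRICLE)] = VENTRICLE
        moved = LabelVolume(label_volume.labels.with_data(data))
        rep = metrics.delineation_report(moved, label_volume).set_index("code")
        assert rep.loc[VENTRICLE, "dsc"] < 1.0
        assert rep.loc[VENTRICLE, "hd_mm"] >= float(
            label_volume.labels.spacing_mm.min())

    def test_missing_organ_flagged_not_scored(self, label_volume):
        data = label_volume.labels.data.copy()
        data[data == VENTRICLE] = 3
        gone = LabelVolume(label_volume.labels.with_data(data))
        rep = metrics.delineation_report(gone, label_volume).set_index("code")
        assert not rep.loc[VENTRICLE, "present"]
        assert np.isnan(rep.loc[VENTRICLE, "dsc"])

    def test_dsc_and_hd_respond_oppositely_to_dilation(self, label_volume):
        truth = label_volume.mask(VENTRICLE)
        spacing = label_volume.labels.spacing_mm
        dscs, hds = [], []
        for its in (1, 2, 3):
            grown = ndimage.binary_dilation(truth, iterations=its)
            dscs.append(metrics.dice_coefficient(grown, truth))
            hds.append(metrics.hausdorff_distance(grown, truth, spacing))
        assert dscs[0] > dscs[1] > dscs[2]
        assert hds[0] <= hds[1] <= hds[2]


class TestPairedComparison:
    def test_constant_shift_matches_exact_enumeration(self, rng):
        x = rng.normal(size=10)
        y = x + 1.0
        out = metrics.paired_model_comparison(y, x)
        want = oracles.wilcoxon_exact_two_sided(y - x)
        assert out["p_value"] == pytest.approx(want, rel=1e-9)

    def test_random_pairs_match_enumeration(self, rng):
        x = rng.normal(size=8)
        y = x + rng.normal(0.3, 1.0, size=8)
        out = metrics.paired_model_comparison(x, y)
        want = oracles.wilcoxon_exact_two_sided(x - y)
        assert out["p_value"] == pytest.approx(want, rel=1e-9)

    def test_equal_models_degenerate(self, rng):
        x = rng.normal(size=6)
        out = metrics.paired_model_comparison(x, x.copy())
        assert out["degenerate"]

    def test_swap_flips_statistic_keeps_p(self, rng):
        x = rng.normal(size=9)
        y = x + rng.normal(0.5, 0.5, size=9)
        a = metrics.paired_model_comparison(x, y)
        b = metrics.paired_model_comparison(y, x)
        assert a["p_value"] == pytest.approx(b["p_value"], rel=1e-12)
        assert a["statistic"] == pytest.approx(-b["statistic"], rel=1e-12)


class TestMaskDiscipline:
    def test_background_corruption_leaves_masked_metrics_unchanged(self, rng):
        a = rng.uniform(0, 1000, size=(9, 9, 9))
        b = a + rng.normal(0, 50, size=(9, 9, 9))
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        a2, b2 = a.copy(), b.copy()
        a2[~mask] = 12345.0
        b2[~mask] = -9999.0
        assert metrics.masked_mae(a, b, mask) == metrics.masked_mae(a2, b2, mask)
        assert metrics.masked_psnr(a, b, mask) == metrics.masked_psnr(a2, b2, mask)
        # ssim windows reach outside the mask by design, so restrict to the
        # deep interior where the 7^3 window stays inside the mask
        core = np.zeros((9, 9, 9), bool)
        core[4, 4, 4] = True
        a3, b3 = a.copy(), b.copy()
        a3[:1] = 7777.0
        b3[:1] = -7777.0
        assert metrics.masked_ssim(a, b, core) == pytest.approx(
            metrics.masked_ssim(a3, b3, core), rel=1e-9)


def test_sharpness_increases_with_high_frequency_content(rng):
    smooth = np.ones((8, 8, 8))
    noisy = smooth + rng.normal(0, 1, size=(8, 8, 8))
    assert metrics.sharpness(noisy) > metrics.sharpness(smooth)
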