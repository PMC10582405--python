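"""Image-quality and vascular quantification metrics."""

import numpy as np
import pytest
from scipy import ndimage

from pavol.metrics import (
    RoiSpec,
    binarize,
    depth_encoded_map,
    fwhm,
    leakage_index,
    mse,
    psnr,
    snr_db,
    ssim,
    vessel_density,
)

from conftest import random_volume


class TestMse:
    def test_identical_volumes_give_zero(self):
        a = random_volume((8, 8, 8), seed=0).data
        assert mse(a, a) == 0.0

    def test_uniform_offset_closed_form(self):
        a = random_volume((8, 8, 8), seed=1).data
        assert mse(a, a + 0.1) == pytest.approx(0.01, rel=1e-5)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(6, 7, 8))
        b = rng.uniform(size=(6, 7, 8))
        brute = sum(
            (a[i, j, k] - b[i, j, k]) ** 2
            for i in range(6) for j in range(7) for k in range(8)
        ) / (6 * 7 * 8)
        assert mse(a, b) == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


class TestPsnr:
    def test_uniform_difference_closed_form(self):
        a = np.zeros((8, 8, 8))
        assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)

    def test_halving_difference_adds_six_db(self):
        a = np.zeros((8, 8, 8))
        assert psnr(a, a + 0.05) - psnr(a, a + 0.1) == pytest.approx(
            20 * np.log10(2), abs=1e-9
        )

    def test_identical_volumes_give_infinity(self):
        a = random_volume((6, 6, 6), seed=3).data
        assert psnr(a, a) == float("inf")

    def test_consistent_with_mse(self):
        a = random_volume((6, 6, 6), seed=4).data
        b = random_volume((6, 6, 6), seed=5).data
        assert psnr(a, b) == pytest.approx(10 * np.log10(1.0 / mse(a, b)), rel=1e-12)


class TestSsim:
    def test_self_similarity_is_one(self):
        a = random_volume((12, 12, 12), seed=6).data
        assert ssim(a, a) == pytest.approx(1.0)

    def test_inverted_volume_scores_below_one(self):
        a = random_volume((12, 12, 12), seed=7).data
        assert ssim(a, 1.0 - a) < 1.0

    def test_symmetry(self):
        a = random_volume((12, 12, 12), seed=8).data
        b = random_volume((12, 12, 12), seed=9).data
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-9)

    def test_single_window_matches_hand_computation(self):
        """For a 7^3 volume with window 7 there is one local window; the score
        reduces to the closed-form SSIM of the global statistics."""
        rng = np.random.default_rng(10)
        a = rng.uniform(size=(7, 7, 7))
        b = rng.uniform(size=(7, 7, 7))
        n = a.size
        mu_a, mu_b = a.mean(), b.mean()
        # unbiased (n-1) normalization for (co)variances
        va = ((a - mu_a) ** 2).sum() / (n - 1)
        vb = ((b - mu_b) ** 2).sum() / (n - 1)
        cov = ((a - mu_a) * (b - mu_b)).sum() / (n - 1)
        c1, c2 = 0.01**2, 0.03**2
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
        )
        assert ssim(a, b, window=7) == pytest.approx(expected, rel=1e-9)

    def test_window_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), window=7)


class TestSnr:
    def _vol(self):
        rng = np.random.default_rng(11)
        data = np.zeros((16, 16, 16))
        data[: 8] = rng.normal(0.0, 0.1, size=(8, 16, 16))
        data[12, 8, 8] = 1.0
        return data

    def test_closed_form(self):
        data = np.zeros((16, 16, 16))
        data[12, 8, 8] = 1.0
        noise = np.zeros((16, 16, 16))
        rng = np.random.default_rng(12)
        data[:8] = rng.normal(0, 0.1, size=(8, 16, 16))
        sig = RoiSpec(box=((8, 16), (0, 16), (0, 16)))
        noi = RoiSpec(box=((0, 8), (0, 16), (0, 16)))
        expected = 20 * np.log10(1.0 / data[:8].std())
        assert snr_db(data, sig, noi) == pytest.approx(expected, rel=1e-9)

    def test_scale_invariance(self):
        data = self._vol()
        sig = RoiSpec(box=((8, 16), (0, 16), (0, 16)))
        noi = RoiSpec(box=((0, 8), (0, 16), (0, 16)))
        assert snr_db(3.0 * data, sig, noi) == pytest.approx(
            snr_db(data, sig, noi), rel=1e-9
        )

    def test_overlapping_rois_rejected(self):
        data = self._vol()
        roi = RoiSpec(box=((0, 16), (0, 16), (0, 16)))
        with pytest.raises(ValueError, match="overlap"):
            snr_db(data, roi, roi)


class TestFwhm:
    def test_gaussian_profile_analytic_width(self):
        """FWHM of a sigma = 1 mm Gaussian is 2 sqrt(2 ln 2) = 2.3548 mm."""
        x = np.arange(-5, 5, 0.05)
        profile = np.exp(-0.5 * x**2)
        assert fwhm(profile, spacing_mm=0.05) == pytest.approx(2.3548, rel=0.01)

    def test_rectangular_profile(self):
        profile = np.zeros(100)
        profile[40:70] = 1.0  # 30 samples at 0.1 mm = 3.0 mm
        assert fwhm(profile, spacing_mm=0.1) == pytest.approx(3.0, abs=0.1)

    def test_scale_law(self):
        x = np.arange(-6, 6, 0.05)
        profile = np.exp(-0.5 * x**2)
        w1 = fwhm(profile, spacing_mm=0.05)
        w2 = fwhm(profile, spacing_mm=0.15)  # dilate the spatial axis by 3
        assert w2 == pytest.approx(3.0 * w1, rel=1e-9)

    def test_matches_brute_force_crossing_search(self):
        """Rasterized 2 mm cylinder cross-section profile: compare against an
        independent half-maximum crossing scan."""
        spacing = 0.1
        x = (np.arange(64) + 0.5) * spacing
        c, r = 3.2, 1.0
        chord = np.where(np.abs(x - c) <= r, np.sqrt(np.maximum(r**2 - (x - c) ** 2, 0)), 0)
        half = chord.max() / 2
        above = np.nonzero(chord >= half)[0]
        lo, hi = above[0], above[-1]

        def interp(i_out, i_in):
            return i_in + (chord[i_in] - half) / (chord[i_in] - chord[i_out]) * (
                i_out - i_in
            )

        brute = (interp(hi + 1, hi) - interp(lo - 1, lo)) * spacing
        assert fwhm(chord, spacing) == pytest.approx(brute, rel=1e-9)

    def test_unpeaked_profile_rejected(self):
        with pytest.raises(ValueError):
            fwhm(np.linspace(0, 1, 50), 0.1)  # no crossing right of the max


class TestDepthMap:
    def test_single_bright_voxel(self):
        vol = np.zeros((10, 6, 6))
        vol[7, 2, 3] = 1.0
        dm = depth_encoded_map(vol, axis="axial")
        assert dm.depth[2, 3] == 7
        assert dm.intensity[2, 3] == 1.0
        assert dm.intensity.sum() == 1.0

    def test_constant_volume_ties_resolve_shallowest(self):
        vol = np.full((10, 6, 6), 0.5)
        dm = depth_encoded_map(vol, axis="axial")
        assert np.all(dm.depth == 0)

    def test_two_planes_deeper_brighter(self):
        vol = np.zeros((10, 6, 6))
        vol[2] = 0.4
        vol[8] = 0.9
        dm = depth_encoded_map(vol, axis="axial")
        assert np.all(dm.depth == 8)
        np.testing.assert_array_equal(dm.intensity, np.max(vol, axis=0))


class TestBinarize:
    def test_zero_volume_all_false(self):
        assert not binarize(np.zeros((4, 4, 4))).any()

    def test_two_level_volume(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 2, 3] = 1.0
        out = binarize(vol, fraction=0.1)
        assert out.sum() == 1 and out[1, 2, 3]

    def test_fixed_fraction_matches_brute_force(self):
        vol = random_volume((8, 8, 8), seed=13).data
        out = binarize(vol, fraction=0.1)
        thresh = 0.1 * vol.max()
        brute = sum(
            vol[i, j, k] > thresh
            for i in range(8) for j in range(8) for k in range(8)
        )
        assert int(out.sum()) == brute

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.ones((4, 4, 4)), fraction=1.5)


class TestLeakageIndex:
    def _tube(self):
        vol = np.zeros((24, 24, 24), dtype=np.float32)
        vol[10:13, 10:13, :] = 1.0
        return vol

    def test_identical_volumes_give_one(self):
        v = self._tube()
        assert leakage_index(v, v) == 1.0

    def test_dilated_input_scores_above_one(self):
        """Dilating a thin tube inflates the input count; the oracle is the
        explicit voxel count ratio after scipy dilation."""
        v = self._tube()
        dilated = ndimage.binary_dilation(v > 0, np.ones((3, 3, 3))).astype(np.float32)
        li = leakage_index(dilated, v)
        oracle = dilated.sum() / (v > 0).sum()
        assert li > 1.0
        assert li == pytest.approx(oracle, rel=1e-12)

    def test_swapping_arguments_gives_reciprocal(self):
        v = self._tube()
        dilated = ndimage.binary_dilation(v > 0, np.ones((3, 3, 3))).astype(np.float32)
        assert leakage_index(v, dilated) == pytest.approx(
            1.0 / leakage_index(dilated, v), rel=1e-12
        )

    def test_empty_output_rejected(self):
        v = self._tube()
        with pytest.raises(ValueError, match="empty"):
            leakage_index(v, np.zeros_like(v))


class TestVesselDensity:
    def test_full_and_empty_rois(self):
        vol = np.ones((8, 8, 8), dtype=bool)
        roi = RoiSpec(box=((0, 8), (0, 8), (0, 8)))
        assert vessel_density(vol, roi) == 1.0
        assert vessel_density(np.zeros((8, 8, 8), bool), roi) == 0.0

    def test_half_filled_box(self):
        vol = np.zeros((8, 8, 8), dtype=bool)
        vol[:4] = True
        roi = RoiSpec(box=((0, 8), (0, 8), (0, 8)))
        assert vessel_density(vol, roi) == 0.5

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError):
            vessel_density(np.ones((4, 4, 4), bool), RoiSpec(box=((0, 8), (0, 4), (0, 4))))
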