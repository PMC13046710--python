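"""Enhancement pipeline: kernels, filter arms, wavelet round-trips,
mean fusion and the denoising property."""

import numpy as np
import pytest

from dermatex.enhance import (GaussianSpec, SubbandSet, clahe, dwt_decompose,
                              filter_arms, gaussian_filter, gaussian_kernel,
                              ictef_enhance, idwt_reconstruct, mean_fuse,
                              wiener_filter)
from dermatex.synthetic import default_class_specs, generate_image


class TestGaussian:
    def test_kernel_matches_closed_form(self):
        """3x3, sigma=1 kernel equals the normalized analytic Gaussian
        evaluated at offsets {-1,0,1}^2."""
        k = gaussian_kernel(GaussianSpec(sigma=1.0, window=3))
        ref = np.empty((3, 3))
        for i, y in enumerate((-1, 0, 1)):
            for j, x in enumerate((-1, 0, 1)):
                ref[i, j] = np.exp(-(x * x + y * y) / 2.0)
        ref /= ref.sum()
        np.testing.assert_allclose(k, ref, atol=1e-12)
        assert abs(k.sum() - 1.0) < 1e-12

    def test_impulse_response_is_kernel(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        out = gaussian_filter(img)
        np.testing.assert_allclose(out[2:5, 2:5], gaussian_kernel(GaussianSpec()),
                                   atol=1e-12)

    def test_constant_preserved(self):
        img = np.full((16, 16), 0.73)
        np.testing.assert_allclose(gaussian_filter(img), img, atol=1e-12)

    def test_variance_reduction_on_noise(self, rng):
        img = rng.random((64, 64))
        assert gaussian_filter(img).var() < img.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            GaussianSpec(window=4)


class TestArms:
    def test_all_arms_preserve_constants(self):
        img = np.full((32, 32), 0.41)
        for arm in filter_arms(img):
            np.testing.assert_allclose(arm, img, atol=1e-9)

    def test_median_arm_restores_salt_pepper(self, rng):
        """Sparse impulse corruption is removed at interior pixels
        (checked against a brute-force 3x3 median)."""
        img = np.full((32, 32), 0.5)
        pos = rng.choice(32 * 32, size=25, replace=False)  # < 1/9 per window
        flat = img.ravel()
        flat[pos[:12]] = 0.0
        flat[pos[12:]] = 1.0
        img = flat.reshape(32, 32)
        _, _, arm_m = filter_arms(img)
        brute = np.empty((30, 30))
        for y in range(30):
            for x in range(30):
                brute[y, x] = np.median(img[y:y + 3, x:x + 3])
        # CLAHE precedes the median; on a 3-valued image it is monotone,
        # so pixels the brute-force median restores must be restored.
        assert np.all(np.abs(arm_m[1:-1, 1:-1][brute == 0.5] - 0.5) < 0.2)

    def test_arms_denoise_smooth_ramp(self, rng):
        clean = np.tile(np.linspace(0.2, 0.8, 64), (64, 1))
        noisy = np.clip(clean + 0.05 * rng.standard_normal(clean.shape), 0, 1)
        base = ((noisy - clean) ** 2).mean()
        arm_g, arm_w, _ = filter_arms(noisy)
        for arm in (arm_g, arm_w):
            assert ((arm - clean) ** 2).mean() < base

    def test_wiener_flat_region_is_smoothed(self, rng):
        noisy = 0.5 + 0.05 * rng.standard_normal((32, 32))
        out = wiener_filter(noisy)
        assert out.var() < noisy.var()

    def test_clahe_constant_passthrough(self):
        img = np.full((32, 32), 0.6)
        np.testing.assert_array_equal(clahe(img), img)


class TestWavelet:
    def test_constant_image_details_vanish(self):
        sb = dwt_decompose(np.full((64, 64), 0.5))
        for lvl in sb.details:
            for c in lvl:
                assert np.abs(c).max() < 1e-10

    def test_round_trip_identity(self, rng):
        img = rng.random((64, 64))
        back = idwt_reconstruct(dwt_decompose(img), clip=False)
        assert np.abs(back - img).max() < 1e-8

    def test_energy_preserved(self, rng):
        """Periodized db2 is orthogonal: coefficient energy equals
        pixel energy."""
        img = rng.random((64, 64))
        sb = dwt_decompose(img)
        energy = (sb.approximation ** 2).sum() + sum(
            (c ** 2).sum() for lvl in sb.details for c in lvl)
        assert abs(energy - (img ** 2).sum()) / (img ** 2).sum() < 1e-6

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError):
            dwt_decompose(np.zeros((32, 32)), wavelet="nosuchwavelet")

    def test_zeroed_details_equals_approximation_reconstruction(self, rng):
        img = rng.random((64, 64))
        sb = dwt_decompose(img)
        zeroed = sb.map(np.zeros_like)
        fused = SubbandSet(approximation=sb.approximation,
                           details=zeroed.details, wavelet=sb.wavelet,
                           levels=sb.levels)
        via_fuse = mean_fuse(fused, fused, fused)
        np.testing.assert_allclose(idwt_reconstruct(via_fuse, clip=False),
                                   idwt_reconstruct(fused, clip=False),
                                   atol=1e-12)


class TestFusion:
    def test_mean_of_identical_is_identity(self, rng):
        sb = dwt_decompose(rng.random((32, 32)))
        fused = mean_fuse(sb, sb, sb)
        np.testing.assert_allclose(fused.approximation, sb.approximation,
                                   atol=1e-12)

    def test_symmetry_under_permutation(self, rng):
        sbs = [dwt_decompose(rng.random((32, 32))) for _ in range(3)]
        a = mean_fuse(sbs[0], sbs[1], sbs[2])
        b = mean_fuse(sbs[2], sbs[0], sbs[1])
        np.testing.assert_allclose(a.approximation, b.approximation, atol=1e-12)
        for la, lb in zip(a.details, b.details):
            for ca, cb in zip(la, lb):
                np.testing.assert_allclose(ca, cb, atol=1e-12)

    def test_elementwise_mean_oracle(self, rng):
        base = dwt_decompose(rng.random((32, 32)))
        s1 = base.map(lambda c: np.full_like(c, 0.3))
        s2 = base.map(lambda c: np.full_like(c, 0.6))
        s3 = base.map(lambda c: np.full_like(c, 0.9))
        fused = mean_fuse(s1, s2, s3)
        np.testing.assert_allclose(fused.approximation, 0.6, atol=1e-12)

    def test_linearity_in_scalar_multiples(self, rng):
        sb = dwt_decompose(rng.random((32, 32)))
        a, b, c = 0.2, 1.0, -0.5
        fused = mean_fuse(sb.map(lambda x: a * x), sb.map(lambda x: b * x),
                          sb.map(lambda x: c * x))
        scale = (a + b + c) / 3.0
        np.testing.assert_allclose(fused.approximation,
                                   scale * sb.approximation, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        sb32 = dwt_decompose(rng.random((32, 32)))
        sb64 = dwt_decompose(rng.random((64, 64)))
        with pytest.raises(ValueError):
            mean_fuse(sb32, sb32, sb64)


class TestICTEF:
    @pytest.mark.parametrize("c", [0.0, 0.37, 1.0])
    def test_constant_idempotence(self, c):
        img = np.full((32, 32, 3), c)
        np.testing.assert_allclose(ictef_enhance(img), img, atol=1e-6)

    def test_output_shape(self, rng):
        img = rng.random((40, 56, 3))
        assert ictef_enhance(img).shape == (40, 56, 3)

    def test_denoising_reduces_mse(self):
        """Enhanced-vs-clean MSE beats noisy-vs-clean MSE on 20 seeded
        noisy textures (sigma = 0.1)."""
        spec = default_class_specs()[1]
        n_better = 0
        for s in range(20):
            clean = generate_image(spec, (64, 64), 0.0, None, seed=s)
            noisy = generate_image(spec, (64, 64), 0.1, None, seed=s)
            enh = ictef_enhance(noisy)
            n_better += ((enh - clean) ** 2).mean() < ((noisy - clean) ** 2).mean()
        assert n_better == 20

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ictef_enhance(np.zeros((4, 4, 3)))
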