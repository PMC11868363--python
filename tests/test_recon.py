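"""Split-Bregman solver, coil combination, SENSE, g-factor, denoising."""

import numpy as np
import pytest

import usirhf as u
from usirhf.errors import IllConditionedError, InvalidParameterError
from usirhf.phantom import zero_filled_recon

from conftest import nrmse


def _kspace_of(image_values):
    return u.fft_centered(np.asarray(image_values, dtype=complex))


class TestSplitBregman:
    def test_full_mask_zero_lambda_equals_ifft(self, small_phantom):
        _, truth = small_phantom
        y = _kspace_of(truth.values)
        mask = u.generate_full_mask(*y.shape)
        x, _ = u.split_bregman_solve(y, mask,
                                     u.ReconConfig(lambda1=0, lambda2=0))
        assert nrmse(x, truth.values) < 1e-8

    def test_zero_data_gives_zero_image(self):
        mask = u.generate_golden_angle_mask(32, 32, 1.7)
        x, info = u.split_bregman_solve(np.zeros((32, 32), complex), mask,
                                        u.ReconConfig())
        assert np.abs(x).max() == 0
        assert info["iterations"] == 0

    def test_beats_zero_filling_on_undersampled_phantom(self,
                                                        small_phantom):
        _, truth = small_phantom
        y = _kspace_of(truth.values)
        mask = u.generate_golden_angle_mask(*y.shape, 1.7)
        ym = np.where(mask.sampled, y, 0)
        x, _ = u.split_bregman_solve(ym, mask, u.ReconConfig())
        zf = u.ifft_centered(ym)
        assert nrmse(x, truth.values) < nrmse(zf, truth.values)

    def test_objective_nonincreasing(self, small_phantom):
        _, truth = small_phantom
        y = _kspace_of(truth.values)
        mask = u.generate_golden_angle_mask(*y.shape, 1.7)
        ym = np.where(mask.sampled, y, 0)
        _, info = u.split_bregman_solve(ym, mask, u.ReconConfig())
        tr = np.asarray(info["objective_trace"])
        assert len(tr) >= 2
        assert np.all(np.diff(tr) <= 1e-6 * tr[:-1])


class TestUsIrhfChain:
    def test_single_coil_full_sampling_oracle(self, small_phantom):
        _, truth = small_phantom
        y = _kspace_of(truth.values)[None]
        mask = u.generate_full_mask(*truth.values.shape)
        ks = u.KSpaceVolume(y, mask, 1)
        sens = np.ones_like(y)
        img = u.reconstruct_us_irhf(
            ks, sens, u.ReconConfig(lambda1=0, lambda2=0,
                                    denoise_strength=0))
        assert nrmse(img.values, np.abs(u.ifft_centered(y[0]))) < 1e-8

    def test_multicoil_noiseless_full_sampling(self, small_phantom):
        _, truth = small_phantom
        coils = u.simulate_coil_profiles(truth.values.shape, 8, 3)
        mask = u.generate_full_mask(*truth.values.shape)
        ks = u.acquire_kspace(truth, coils, mask, 0.0, 0)
        img = u.reconstruct_us_irhf(
            ks, coils.maps, u.ReconConfig(lambda1=0, lambda2=0,
                                          denoise_strength=0))
        assert nrmse(img.values, truth.values) < 0.01

    def test_undersampled_noisy_beats_zero_filling(self, small_phantom):
        _, truth = small_phantom
        coils = u.simulate_coil_profiles(truth.values.shape, 8, 3)
        mask = u.generate_golden_angle_mask(*truth.values.shape, 1.7)
        clean = u.acquire_kspace(truth, coils, mask, 0.0, 0)
        sigma = u.sigma_for_snr(clean.data, mask, 30.0)
        ks = u.acquire_kspace(truth, coils, mask, sigma, 0)
        img = u.reconstruct_us_irhf(ks, coils.maps, u.ReconConfig())
        # normalize out the coil-combination vs RSS intensity convention
        zf = zero_filled_recon(ks)
        t = truth.values
        err = nrmse(img.values, t)
        err_zf = nrmse(zf * t.mean() / zf.mean(), t)
        assert err < err_zf

    def test_nrmse_improves_with_sampling(self, small_phantom):
        _, truth = small_phantom
        coils = u.simulate_coil_profiles(truth.values.shape, 8, 3)
        errs = []
        for factor in (1.0, 1.7, 3.0):
            mask = u.generate_golden_angle_mask(*truth.values.shape,
                                                factor)
            clean = u.acquire_kspace(truth, coils, mask, 0.0, 0)
            sigma = u.sigma_for_snr(clean.data, mask, 30.0)
            ks = u.acquire_kspace(truth, coils, mask, sigma, 0)
            img = u.reconstruct_us_irhf(ks, coils.maps, u.ReconConfig())
            errs.append(nrmse(img.values, truth.values))
        assert errs[0] <= errs[1] <= errs[2]

    def test_coil_count_mismatch(self, small_phantom):
        _, truth = small_phantom
        y = _kspace_of(truth.values)[None]
        mask = u.generate_full_mask(*truth.values.shape)
        ks = u.KSpaceVolume(y, mask, 1)
        with pytest.raises(Exception):
            u.reconstruct_us_irhf(ks, np.ones((2,) + y.shape[1:]),
                                  u.ReconConfig())


class TestConventionalSense:
    def test_factor_one_is_rss(self, small_phantom):
        _, truth = small_phantom
        coils = u.simulate_coil_profiles(truth.values.shape, 4, 3)
        mask = u.generate_cartesian_mask(*truth.values.shape, 1.0, 1.0)
        ks = u.acquire_kspace(truth, coils, mask, 0.0, 0)
        img = u.reconstruct_conventional(ks, coils.maps)
        rss = zero_filled_recon(ks)
        assert np.abs(img.values - rss).max() < 1e-12

    def test_factor_three_exact_unfolding(self, small_phantom):
        _, truth = small_phantom
        coils = u.simulate_coil_profiles(truth.values.shape, 8, 3)
        mask = u.generate_cartesian_mask(*truth.values.shape, 3.0, 1.0)
        ks = u.acquire_kspace(truth, coils, mask, 0.0, 0)
        img = u.reconstruct_conventional(ks, coils.maps)
        assert nrmse(img.values, truth.values) < 0.02

    def test_single_coil_factor_three_unresolvable(self, small_phantom):
        _, truth = small_phantom
        coils = u.simulate_coil_profiles(truth.values.shape, 1, 3)
        mask = u.generate_cartesian_mask(*truth.values.shape, 3.0, 1.0)
        ks = u.acquire_kspace(truth, coils, mask, 0.0, 0)
        with pytest.raises(IllConditionedError):
            u.reconstruct_conventional(ks, coils.maps)

    def test_requires_cartesian_mask(self, small_phantom):
        _, truth = small_phantom
        mask = u.generate_golden_angle_mask(*truth.values.shape, 1.7)
        y = np.where(mask.sampled, _kspace_of(truth.values), 0)[None]
        ks = u.KSpaceVolume(y, mask, 1)
        with pytest.raises(InvalidParameterError):
            u.reconstruct_conventional(ks, np.ones_like(y))


class TestGFactor:
    def test_factor_one_all_ones(self):
        sens = u.simulate_coil_profiles((24, 24), 4, 0).maps
        assert np.all(u.gfactor_map(sens, 1.0).values == 1.0)

    def test_orthogonal_coils_give_unit_g(self):
        sens = np.zeros((2, 8, 8), complex)
        sens[0, :4] = 1.0
        sens[1, 4:] = 1.0
        g = u.gfactor_map(sens, 2.0)
        assert np.allclose(g.values, 1.0, atol=1e-6)

    def test_identical_coils_hit_cap(self):
        sens = np.ones((2, 8, 8), complex)
        g = u.gfactor_map(sens, 2.0, cap=50.0)
        assert g.values.max() == 50.0

    def test_g_at_least_one(self):
        sens = u.simulate_coil_profiles((24, 24), 6, 1).maps
        g = u.gfactor_map(sens, 3.0)
        assert np.all(g.values >= 1.0)


class TestGFactorWeightedDenoise:
    def test_strength_zero_is_identity(self):
        img = u.ImageVolume(np.random.default_rng(0).random((32, 32)),
                            280.0, (1.0, 1.0))
        out = u.gfactor_weighted_denoise(
            img, u.GFactorMap(np.ones((32, 32))), 0.0)
        assert out is img

    def test_constant_image_preserved(self):
        img = u.ImageVolume(np.full((32, 32), 7.0), 280.0, (1.0, 1.0))
        out = u.gfactor_weighted_denoise(
            img, u.GFactorMap(np.ones((32, 32))), 2.0)
        assert np.abs(out.values / 7.0 - 1).max() < 0.01

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        img = u.ImageVolume(5.0 + rng.normal(0, 0.1, (64, 64)),
                            280.0, (1.0, 1.0))
        out = u.gfactor_weighted_denoise(
            img, u.GFactorMap(np.ones((64, 64))), 1.0)
        assert out.values.var() < img.values.var()
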