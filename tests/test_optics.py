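import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.fft import fft2, ifft2
from scipy.ndimage import gaussian_filter

from vesselqpi.config import OpticalConfig
from vesselqpi import optics


def band_limited_phase(shape=(128, 128), sigma=3.0, amplitude=0.3, seed=0):
    rng = np.random.default_rng(seed)
    phi = gaussian_filter(rng.normal(size=shape), sigma)
    phi -= phi.mean()
    phi *= amplitude / np.abs(phi).max()
    return phi


class TestTransferFunctions:
    def test_dc_null(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        assert tfs.h_x[0, 0] == 0
        assert tfs.h_y[0, 0] == 0

    def test_antisymmetry(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        for h in (tfs.h_x, tfs.h_y):
            neg = np.roll(h[::-1, ::-1], shift=(1, 1), axis=(0, 1))
            np.testing.assert_allclose(h + neg, 0, atol=1e-15)

    def test_purely_imaginary(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        assert np.allclose(tfs.h_x.real, 0, atol=1e-12)
        assert np.allclose(tfs.h_y.real, 0, atol=1e-12)

    def test_passband_grows_with_na(self):
        # low NA so doubling stays under the grid Nyquist
        lo = OpticalConfig(numerical_aperture=0.2)
        hi = OpticalConfig(numerical_aperture=0.4)
        shape = (128, 128)
        n_lo = np.count_nonzero(
            np.abs(optics.compute_transfer_functions(lo, shape).h_x) > 1e-6
        )
        n_hi = np.count_nonzero(
            np.abs(optics.compute_transfer_functions(hi, shape).h_x) > 1e-6
        )
        assert n_hi > n_lo

    def test_support_bounded_by_partially_coherent_cutoff(self):
        config = OpticalConfig(numerical_aperture=0.3, pixel_size=0.5)
        tfs = optics.compute_transfer_functions(config, (128, 128))
        fy = np.fft.fftfreq(128, d=0.5)
        fx = np.fft.fftfreq(128, d=0.5)
        FX, FY = np.meshgrid(fx, fy)
        rho = np.hypot(FX, FY)
        cutoff = 2 * config.numerical_aperture / config.wavelength
        assert np.all(np.abs(tfs.h_x)[rho > cutoff + 1e-9] == 0)

    def test_rejects_tiny_grid(self, optical_config):
        with pytest.raises(ValueError):
            optics.compute_transfer_functions(optical_config, (4, 4))

    def test_rejects_empty_passband(self):
        config = OpticalConfig(numerical_aperture=0.01, pixel_size=0.1)
        with pytest.raises(ValueError, match="passband"):
            optics.compute_transfer_functions(config, (8, 8))


class TestFormDPC:
    def _quad(self, i0, i90, i180, i270):
        return optics.RawIntensityQuad(
            images={0: i0, 90: i90, 180: i180, 270: i270}
        )

    def test_equal_pairs_give_zero(self):
        ones = np.ones((8, 8))
        dpc = optics.form_dpc(self._quad(ones, ones, ones.copy(), ones.copy()))
        assert np.all(dpc.dpc_x == 0) and np.all(dpc.dpc_y == 0)

    def test_three_vs_one_gives_half(self):
        a, b = 3 * np.ones((8, 8)), np.ones((8, 8))
        dpc = optics.form_dpc(self._quad(a, b.copy(), b, a.copy()))
        np.testing.assert_allclose(dpc.dpc_x, 0.5)
        np.testing.assert_allclose(dpc.dpc_y, -0.5)

    def test_zero_sum_pixels_flagged(self):
        z = np.zeros((8, 8))
        dpc = optics.form_dpc(self._quad(z, z, z, z))
        assert np.all(dpc.dpc_x == 0)
        assert dpc.zero_sum_mask.all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            self._quad(
                np.ones((8, 8)), np.ones((8, 8)), np.ones((8, 9)), np.ones((8, 8))
            )

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_for_nonnegative_quads(self, seed):
        rng = np.random.default_rng(seed)
        imgs = [rng.uniform(0, 10, size=(16, 16)) for _ in range(4)]
        dpc = optics.form_dpc(self._quad(*imgs))
        assert np.all(np.abs(dpc.dpc_x) <= 1)
        assert np.all(np.abs(dpc.dpc_y) <= 1)


class TestSimulateAcquisition:
    def test_zero_phase_noiseless_images_equal(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        phase = optics.PhaseImage(np.zeros((64, 64)), optical_config.pixel_size)
        quad = optics.simulate_acquisition(phase, tfs)
        imgs = list(quad.images.values())
        for im in imgs[1:]:
            np.testing.assert_array_equal(im, imgs[0])

    def test_same_seed_identical_noise(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        phase = optics.PhaseImage(
            band_limited_phase((64, 64)), optical_config.pixel_size
        )
        q1 = optics.simulate_acquisition(phase, tfs, photon_budget=1e4, seed=3)
        q2 = optics.simulate_acquisition(phase, tfs, photon_budget=1e4, seed=3)
        for az in optics.AZIMUTHS:
            np.testing.assert_array_equal(q1.images[az], q2.images[az])

    def test_weak_phase_violation_rejected(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        phase = optics.PhaseImage(
            band_limited_phase((64, 64), amplitude=50.0), optical_config.pixel_size
        )
        with pytest.raises(optics.WeakPhaseError):
            optics.simulate_acquisition(phase, tfs)


class TestRecoverPhase:
    def test_zero_dpc_gives_zero_phase(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        dpc = optics.DPCPair(np.zeros((64, 64)), np.zeros((64, 64)))
        phi = optics.recover_phase(dpc, tfs, alpha=1e-3)
        assert np.all(phi.grid == 0)

    def test_round_trip_noiseless(self, optical_config):
        phi = band_limited_phase((128, 128), seed=1)
        tfs = optics.compute_transfer_functions(optical_config, phi.shape)
        phase = optics.PhaseImage(phi, optical_config.pixel_size)
        quad = optics.simulate_acquisition(phase, tfs)
        rec = optics.recover_phase(optics.form_dpc(quad), tfs, alpha=1e-6)
        r = np.corrcoef(phi.ravel(), rec.grid.ravel())[0, 1]
        assert r >= 0.99
        err = np.linalg.norm(rec.grid - phi) / np.linalg.norm(phi)
        assert err <= 0.05

    def test_band_limited_identity_small_alpha(self, optical_config):
        # forward-then-inverse equals band-pass filtering of the input
        phi = band_limited_phase((128, 128), sigma=4.0, seed=2)
        tfs = optics.compute_transfer_functions(optical_config, phi.shape)
        phase = optics.PhaseImage(phi, optical_config.pixel_size)
        quad = optics.simulate_acquisition(phase, tfs)
        rec = optics.recover_phase(optics.form_dpc(quad), tfs, alpha=1e-10)
        band = (np.abs(tfs.h_x) ** 2 + np.abs(tfs.h_y) ** 2) > 1e-10
        phi_band = ifft2(fft2(phi) * band).real
        err = np.linalg.norm(rec.grid - phi_band) / np.linalg.norm(phi_band)
        assert err <= 1e-3

    def test_linearity(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        rng = np.random.default_rng(0)
        d1 = optics.DPCPair(rng.normal(size=(64, 64)), rng.normal(size=(64, 64)))
        d2 = optics.DPCPair(rng.normal(size=(64, 64)), rng.normal(size=(64, 64)))
        dsum = optics.DPCPair(d1.dpc_x + d2.dpc_x, d1.dpc_y + d2.dpc_y)
        p1 = optics.recover_phase(d1, tfs, alpha=1e-3).grid
        p2 = optics.recover_phase(d2, tfs, alpha=1e-3).grid
        ps = optics.recover_phase(dsum, tfs, alpha=1e-3).grid
        np.testing.assert_allclose(ps, p1 + p2, atol=1e-10)

    def test_variance_non_increasing_in_alpha(self, optical_config):
        phi = band_limited_phase((64, 64), seed=3)
        tfs = optics.compute_transfer_functions(optical_config, phi.shape)
        phase = optics.PhaseImage(phi, optical_config.pixel_size)
        quad = optics.simulate_acquisition(phase, tfs, photon_budget=1e3, seed=0)
        dpc = optics.form_dpc(quad)
        variances = [
            optics.recover_phase(dpc, tfs, alpha=a).grid.var()
            for a in (1e-4, 1e-2, 1.0)
        ]
        assert variances[0] >= variances[1] >= variances[2]

    def test_noise_robustness_with_budget(self, optical_config):
        phi = band_limited_phase((64, 64), seed=4)
        tfs = optics.compute_transfer_functions(optical_config, phi.shape)
        phase = optics.PhaseImage(phi, optical_config.pixel_size)
        rmse_by_budget = []
        for budget in (1e2, 1e3, 1e4):
            errs = []
            for seed in range(3):
                quad = optics.simulate_acquisition(
                    phase, tfs, photon_budget=budget, seed=seed
                )
                rec = optics.recover_phase(optics.form_dpc(quad), tfs, alpha=1e-3)
                errs.append(np.sqrt(np.mean((rec.grid - phi) ** 2)))
            rmse_by_budget.append(np.mean(errs))
        assert rmse_by_budget[0] > rmse_by_budget[1] > rmse_by_budget[2]

    def test_alpha_must_be_positive(self, optical_config):
        tfs = optics.compute_transfer_functions(optical_config, (64, 64))
        dpc = optics.DPCPair(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.raises(ValueError):
            optics.recover_phase(dpc, tfs, alpha=0.0)


class TestPhaseRIConversion:
    def test_zero_phase_gives_medium_ri(self, optical_config):
        phase = optics.PhaseImage(np.zeros((8, 8)), optical_config.pixel_size)
        ri = optics.phase_to_ri(phase, optical_config)
        np.testing.assert_array_equal(ri, 1.3440)

    def test_algebraic_identity_unit_delta_n(self, optical_config):
        dphi = 2 * np.pi * optical_config.slice_thickness_dz / optical_config.wavelength
        phase = optics.PhaseImage(np.full((4, 4), dphi), optical_config.pixel_size)
        ri = optics.phase_to_ri(phase, optical_config)
        np.testing.assert_allclose(ri - optical_config.medium_ri_nm, 1.0)

    def test_one_radian_oracle(self, optical_config):
        # independent arithmetic: 0.72 / (2π · 3.2)
        phase = optics.PhaseImage(np.ones((4, 4)), optical_config.pixel_size)
        ri = optics.phase_to_ri(phase, optical_config)
        expected = 0.72 / (2 * np.pi * 3.2)
        np.testing.assert_allclose(ri - 1.3440, expected, rtol=1e-12)
        assert abs(expected - 0.03580986219567645) < 1e-15

    def test_inverse_round_trip_machine_precision(self, optical_config):
        rng = np.random.default_rng(0)
        ri = 1.3440 + rng.normal(scale=0.01, size=(32, 32))
        phase = optics.ri_to_phase(ri, optical_config)
        back = optics.phase_to_ri(phase, optical_config)
        np.testing.assert_allclose(back, ri, rtol=1e-14, atol=1e-14)

    def test_medium_ri_gives_zero_phase(self, optical_config):
        phase = optics.ri_to_phase(np.full((4, 4), 1.3440), optical_config)
        np.testing.assert_array_equal(phase.grid, 0.0)

    def test_delta_n_001_oracle(self, optical_config):
        phase = optics.ri_to_phase(np.full((4, 4), 1.3440 + 0.01), optical_config)
        np.testing.assert_allclose(phase.grid, 0.2792526803190927, rtol=1e-12)
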