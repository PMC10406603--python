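import numpy as np
import pytest

from _util import center_phase_error
from sim3d._fft import ft3
from sim3d.estimation import (CorrelationSurface, EstimationConfig,
                              EstimationError, Source, cross_correlation_map,
                              estimate_pattern, locate_peak_subpixel)
from sim3d.otf import compute_psf, psf_to_otf
from sim3d.separation import separate_bands
from sim3d.simulator import SimConfig, make_phantom, simulate_raw_stack

EQUAL5 = 2 * np.pi * np.arange(5) / 5


def random_spectrum(shape, seed):
    rng = np.random.default_rng(seed)
    return ft3(rng.normal(size=shape) + 1j * rng.normal(size=shape))


class TestCrossCorrelationMap:
    def test_constructed_integer_shift(self):
        ref = random_spectrum((4, 32, 32), 0)
        moved = np.roll(ref, (5, 3), axis=(1, 2))   # B(k - (5, 3) samples)
        surf = cross_correlation_map(ref, moved)
        iy, ix = np.unravel_index(np.argmax(np.abs(surf.values)),
                                  surf.values.shape)
        assert (iy - 16, ix - 16) == (5, 3)

    def test_zero_shift_autocorrelation(self):
        ref = random_spectrum((4, 32, 32), 1)
        surf = cross_correlation_map(ref, ref)
        iy, ix = np.unravel_index(np.argmax(np.abs(surf.values)),
                                  surf.values.shape)
        peak = surf.values[iy, ix]
        assert (iy, ix) == (16, 16)
        assert peak.real > 0 and abs(peak.imag) < 1e-9 * peak.real

    def test_uncorrelated_spectra_have_no_dominant_peak(self):
        # Monte-Carlo null: contrast ratio stays near 1
        yy, xx = np.ogrid[:32, :32]
        interior = np.hypot(yy - 16, xx - 16) < 12
        contrasts = []
        for seed in range(20):
            a = random_spectrum((2, 32, 32), 100 + seed)
            b = random_spectrum((2, 32, 32), 200 + seed)
            surf = cross_correlation_map(a, b)
            _, _, contrast = locate_peak_subpixel(surf, search_mask=interior)
            contrasts.append(contrast)
        # no dominant peak: the strongest null fluctuation stays below the
        # second-order acceptance threshold (max-selection inflates the
        # annulus-median ratio to ~3 even for pure noise)
        assert np.median(contrasts) < 4.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation_map(np.ones((2, 8, 8)), np.ones((2, 8, 4)))

    def test_empty_overlap_rejected(self):
        z = np.zeros((2, 8, 8), complex)
        with pytest.raises(ValueError, match="overlap"):
            cross_correlation_map(z, z)


class TestLocatePeak:
    def test_pure_pattern_frequency_recovered_subpixel(self):
        # ground-truth oracle: band1 = texture * exp(2 pi i f x)
        f = 0.1837
        rng = np.random.default_rng(5)
        texture = rng.random((1, 256, 256))
        x = np.arange(256)[None, None, :]
        b0 = ft3(texture)
        b1 = ft3(texture * np.exp(2j * np.pi * f * x))
        surf = cross_correlation_map(b0, b1)
        shift, _, _ = locate_peak_subpixel(surf, upsample=20)
        assert abs(shift[1] / 256 - f) < 5e-4
        assert abs(shift[0] / 256) < 5e-4

    def test_twin_peaks_tie_break_lexicographic(self):
        from scipy import fft as spfft
        vals = np.zeros((33, 33), complex)
        vals[10, 20] = vals[20, 10] = 1.0    # equal peaks
        surf = CorrelationSurface(spfft.ifft2(spfft.ifftshift(vals)))
        shift, _, _ = locate_peak_subpixel(surf, upsample=4)
        # row-major argmax: lexicographically smaller (ky, kx) wins
        assert tuple(np.round(shift).astype(int)) == (10 - 16, 20 - 16)

    def test_flat_surface_contrast_one_unreliable(self):
        from scipy import fft as spfft
        vals = np.ones((17, 17), complex)
        surf = CorrelationSurface(spfft.ifft2(spfft.ifftshift(vals)))
        _, _, contrast = locate_peak_subpixel(surf, upsample=1)
        assert contrast == pytest.approx(1.0)


class TestEstimatePattern:
    def _estimate(self, stack, config=None):
        geom = stack.geometry
        nzyx = stack.data.shape[2:]
        psf = compute_psf(geom, nzyx)
        otf = psf_to_otf(psf, geom)
        out = []
        for a in range(geom.n_angles):
            bs = separate_bands(stack.data[a].astype(np.float64), EQUAL5,
                                geometry=geom, angle_index=a)
            out.append(estimate_pattern(bs, otf, config))
        return out

    def test_clean_recovery_second_order(self, world_noiseless):
        stack, truth, _ = world_noiseless
        for prm, t in zip(self._estimate(stack), truth):
            assert prm.source is Source.SECOND_ORDER
            assert np.hypot(*(prm.p - t.p)) < 0.002
            assert center_phase_error(prm.p, prm.phi0, t.p, t.phi0,
                                      (128, 128)) < 0.05
            assert prm.m1 == pytest.approx(2 / 3, abs=0.15)
            assert prm.m2 == pytest.approx(1 / 6, abs=0.1)

    def test_extremely_low_snr_falls_back_to_first_order(self):
        cfg = SimConfig(seed=3, peak_photons=5.0, read_noise_sd=0.0)
        gt = make_phantom("filaments", (8, 128, 128), seed=3)
        stack, truth = simulate_raw_stack(gt, cfg)
        params = self._estimate(stack)
        sources = [p.source for p in params]
        assert sources.count(Source.FIRST_ORDER_FALLBACK) >= 2
        for prm, t in zip(params, truth):
            assert np.hypot(*(prm.p - t.p)) < 0.01

    def test_zero_modulation_raises(self):
        cfg = SimConfig(seed=1, peak_photons=200.0,
                        modulation_m1=0.0, modulation_m2=0.0)
        gt = make_phantom("filaments", (8, 64, 64), seed=1)
        stack, _ = simulate_raw_stack(gt, cfg)
        with pytest.raises(EstimationError):
            self._estimate(stack)

    def test_force_fallback_flag(self, world_noiseless):
        stack, _, _ = world_noiseless
        params = self._estimate(
            stack, EstimationConfig(force_fallback=True))
        assert all(p.source is Source.FIRST_ORDER_FALLBACK for p in params)

    def test_freq_override_skips_search(self, world_noiseless):
        stack, truth, _ = world_noiseless
        geom = stack.geometry
        psf = compute_psf(geom, stack.data.shape[2:])
        otf = psf_to_otf(psf, geom)
        bs = separate_bands(stack.data[0].astype(np.float64), EQUAL5,
                            geometry=geom, angle_index=0)
        prm = estimate_pattern(bs, otf, freq_override=tuple(truth[0].p))
        assert np.allclose(prm.p, truth[0].p)
        assert prm.reliability == np.inf

    @pytest.mark.parametrize("phi0", [0.0, 2 * np.pi / 5, 4 * np.pi / 5,
                                      6 * np.pi / 5, 8 * np.pi / 5])
    def test_phase_sweep_recovery(self, phi0):
        cfg = SimConfig(seed=2, peak_photons=None,
                        initial_phases=(phi0, phi0, phi0))
        gt = make_phantom("filaments", (8, 64, 64), seed=2)
        stack, truth = simulate_raw_stack(gt, cfg)
        prm = self._estimate(stack)[0]
        assert center_phase_error(prm.p, prm.phi0, truth[0].p, phi0,
                                  (64, 64)) < 0.05

    def test_angle_separations_recovered(self, world_noiseless):
        stack, _, _ = world_noiseless
        params = self._estimate(stack)
        az = [p.azimuth for p in params]
        for i, j in ((0, 1), (1, 2), (0, 2)):
            sep = np.degrees(abs(az[i] - az[j])) % 180.0
            expected = 60.0 * abs(i - j)
            assert min(sep, 180 - sep) == pytest.approx(
                min(expected, 180 - expected), abs=0.5)

    def test_frequency_error_degrades_with_photon_count(self):
        # median over seeds: error at 50 photons >= error at 500 photons
        errs = {50.0: [], 500.0: []}
        for photons in errs:
            for seed in range(6):
                cfg = SimConfig(seed=seed, peak_photons=photons)
                gt = make_phantom("filaments", (8, 64, 64), seed=seed)
                stack, truth = simulate_raw_stack(gt, cfg)
                for prm, t in zip(self._estimate(stack), truth):
                    errs[photons].append(np.hypot(*(prm.p - t.p)))
        assert np.median(errs[50.0]) >= np.median(errs[500.0])
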