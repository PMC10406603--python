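import numpy as np
import pytest

from sim3d._fft import embed_lateral, ft3, ift3
from sim3d.assembly import (ReconstructConfig, assemble_spectrum, reconstruct,
                            shift_band, wiener_combine)
from sim3d.data_model import widefield
from sim3d.estimation import PatternParams, Source
from sim3d.filters import FilterSpec
from sim3d.otf import band_otf, compute_psf, psf_to_otf
from sim3d.separation import ORDERS, BandSet, separate_bands
from sim3d.simulator import SimConfig, make_phantom, simulate_raw_stack


def random_spectrum(shape, seed):
    rng = np.random.default_rng(seed)
    return ft3(rng.normal(size=shape))


class TestShiftBand:
    def test_zero_shift_identity(self):
        b = random_spectrum((4, 16, 16), 0)
        assert np.abs(shift_band(b, (0.0, 0.0)) - b).max() < 1e-10

    def test_single_peak_relocated_to_dc(self):
        nz, ny, nx = 4, 64, 64
        f = 10.25 / ny                       # fractional frequency
        x = np.arange(nx)[None, None, :]
        vol = np.exp(2j * np.pi * f * x) * np.ones((nz, ny, 1))
        spec = ft3(vol)
        shifted = shift_band(spec, (0.0, f))  # B(k + f) puts peak at DC
        iz, iy, ix = np.unravel_index(np.argmax(np.abs(shifted)), spec.shape)
        assert (iy, ix) == (ny // 2, nx // 2)

    def test_shift_then_inverse_shift(self):
        b = random_spectrum((4, 16, 16), 1)
        back = shift_band(shift_band(b, (0.07, -0.11)), (-0.07, 0.11))
        assert np.abs(back - b).max() < 1e-9 * np.abs(b).max()

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            shift_band(random_spectrum((2, 8, 8), 2), (0.6, 0.0))


def _single_band_setup(seed=0, shape=(8, 32, 32)):
    """One angle, only the zero band populated."""
    from sim3d.data_model import AcquisitionGeometry

    geom = AcquisitionGeometry(n_angles=1)
    rng = np.random.default_rng(seed)
    vol = rng.random(shape)
    psf = compute_psf(geom, shape)
    spec0 = ft3(vol)
    bands = {m: (spec0 if m == 0 else np.zeros_like(spec0)) for m in ORDERS}
    bs = BandSet(bands=bands, angle_index=0, geometry=geom,
                 phases=2 * np.pi * np.arange(5) / 5)
    otf = psf_to_otf(psf, geom)
    # zero side-band weights: the combination must reduce to a plain
    # single-band Wiener quotient
    prm = PatternParams(p=np.array([0.0, 0.3]), q_z=0.2, phi0=0.0,
                        m1=0.0, m2=0.0, source=Source.SECOND_ORDER,
                        reliability=10.0)
    return bs, otf, prm


class TestWienerCombine:
    def test_single_band_matches_wiener_quotient(self):
        # closed-form oracle: with only the zero band, no notch/apo, tiny w,
        # the combination is a plain Wiener deconvolution of that band
        bs, otf, prm = _single_band_setup()
        w = 1e-6
        spec = FilterSpec(wiener_w=w, flatten_spectrum=False)
        asm = wiener_combine([bs], [prm], otf, spec,
                             notch_enabled=False, apo_enabled=False)
        from sim3d.assembly import _zero_nyquist
        o_pad = band_otf(otf, 0).astype(complex)
        b_pad = embed_lateral(bs[0])
        _zero_nyquist(b_pad, bs[0].shape, 2)
        oracle = np.conj(o_pad) * b_pad / (np.abs(o_pad) ** 2 + w**2)
        scale = np.abs(oracle).max()
        assert np.abs(asm.values - oracle).max() < 1e-6 * scale

    def test_support_mask_independent_of_depths(self, bands_noiseless,
                                                otf_default):
        bandsets, truth = bands_noiseless
        lo = [PatternParams(p=t.p, q_z=t.q_z, phi0=t.phi0, m1=0.15, m2=0.15,
                            source=t.source, reliability=1.0) for t in truth]
        hi = [PatternParams(p=t.p, q_z=t.q_z, phi0=t.phi0, m1=1.0, m2=1.0,
                            source=t.source, reliability=1.0) for t in truth]
        asm_lo = wiener_combine(bandsets, lo, otf_default)
        asm_hi = wiener_combine(bandsets, hi, otf_default)
        assert np.array_equal(asm_lo.effective_support,
                              asm_hi.effective_support)

    def test_real_inverse_for_conjugate_symmetric_input(
            self, bands_noiseless, otf_default):
        bandsets, truth = bands_noiseless
        asm = wiener_combine(bandsets, list(truth), otf_default)
        vol = ift3(asm.values)
        assert np.abs(vol.imag).max() < 1e-6 * np.abs(vol).max()

    def test_empty_band_list_rejected(self, otf_default):
        with pytest.raises(ValueError):
            wiener_combine([], [], otf_default)


class TestReconstruct:
    def test_output_is_2x_lateral(self, world500):
        stack, _, _ = world500
        rec = reconstruct(stack)
        assert rec.volume.shape == (8, 256, 256)

    def test_bit_identical_across_runs(self, world500):
        stack, _, _ = world500
        r1 = reconstruct(stack)
        r2 = reconstruct(stack)
        assert np.array_equal(r1.volume, r2.volume)

    def test_widefield_fallback_equals_deconvolved_widefield(self,
                                                             world_noiseless):
        # with the side bands zeroed the pipeline must collapse to a Wiener
        # deconvolution of the (tapered) widefield image
        stack, truth, _ = world_noiseless
        geom = stack.geometry
        phases = 2 * np.pi * np.arange(5) / 5
        psf = compute_psf(geom, stack.data.shape[2:])
        otf = psf_to_otf(psf, geom)
        bandsets = []
        for a in range(geom.n_angles):
            bs = separate_bands(stack.data[a].astype(np.float64), phases,
                                geometry=geom, angle_index=a)
            for m in (-2, -1, 1, 2):
                bs.bands[m] = np.zeros_like(bs.bands[m])
            bandsets.append(bs)
        params = [PatternParams(p=t.p, q_z=t.q_z, phi0=t.phi0, m1=0.0,
                                m2=0.0, source=t.source, reliability=1.0)
                  for t in truth]
        w = 0.05
        spec = FilterSpec(wiener_w=w, flatten_spectrum=False)
        asm = wiener_combine(bandsets, params, otf, spec,
                             notch_enabled=False, apo_enabled=False)
        from sim3d.assembly import _zero_nyquist
        o_pad = band_otf(otf, 0).astype(complex)
        num = np.zeros_like(o_pad)
        for bs in bandsets:
            b_pad = embed_lateral(bs[0])
            _zero_nyquist(b_pad, bs[0].shape, 2)
            num += np.conj(o_pad) * b_pad
        oracle = num / (3 * np.abs(o_pad) ** 2 + w**2)
        assert np.abs(asm.values - oracle).max() < 1e-6 * np.abs(oracle).max()

    def test_energy_sanity_across_snr_ladder(self):
        # no runaway amplification: total reconstructed intensity within a
        # factor 2 of the input total across the SNR ladder (known pattern
        # parameters so the property is about the combination, not detection)
        gt = make_phantom("filaments", (8, 64, 64), seed=4)
        for photons in (5.0, 20.0, 100.0, 500.0):
            cfg = SimConfig(seed=4, peak_photons=photons)
            stack, truth = simulate_raw_stack(gt, cfg)
            rc = ReconstructConfig(
                clip_negatives=False, notch_enabled=False,
                freq_override=[tuple(t.p) for t in truth],
                phase_override=[t.phi0 for t in truth])
            rec = reconstruct(stack, rc)
            ratio = rec.volume.sum() / stack.data.mean(axis=(0, 1)).sum()
            assert 0.5 < ratio < 2.0, (photons, ratio)

    def test_support_extends_past_widefield_cutoff(self, world500,
                                                   otf_default):
        stack, _, _ = world500
        asm, params, _ = assemble_spectrum(stack)
        kc = otf_default.k_cutoff_lateral_px
        ny = 128
        f = (np.arange(2 * ny) - ny) / ny
        r = np.hypot(f[:, None], f[None, :])
        ring = (np.abs(r - 1.5 * kc) < 0.02)
        assert asm.effective_support[:, ring].any()

    def test_nan_stack_rejected(self, world500):
        stack, _, _ = world500
        bad = type(stack)(data=stack.data.copy(), geometry=stack.geometry)
        bad.data[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="invalid stack"):
            reconstruct(bad)

    def test_provenance_records_parameters(self, world500):
        stack, _, _ = world500
        rec = reconstruct(stack)
        prov = rec.provenance
        assert len(prov["pattern_params"]) == 3
        assert "wiener_w" in prov["config"]
        assert prov["clipped_negative_fraction"] >= 0.0
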