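"""Depth reconstruction and fixed-pattern spatial filtering."""

import numpy as np
import pytest

from stoct import (
    OpticalConfig,
    SpectralStack,
    apply_spatial_filter,
    estimate_fixed_pattern_filter,
    fit_attenuation_profile,
    generate_phase_mask,
    make_phantom,
    reconstruct_depth,
    remove_dc,
    simulate_stack,
)
from stoct.recon import FixedPatternFilter, _point_reflect


def _mirror_stack(config, z0):
    ph = make_phantom("plane_behind_diffuser", config, mu=0.0, z_plane=z0)
    flat = generate_phase_mask(config, "flat", 0)
    return remove_dc(simulate_stack(ph, config, flat, crosstalk=False), "mean_subtract")


class TestReconstructDepth:
    def test_peak_at_reflector_depth_every_pixel(self, spectral_config):
        z0 = 200.0
        vol = reconstruct_depth(_mirror_stack(spectral_config, z0), pad_factor=2)
        dz = vol.z_axis[1] - vol.z_axis[0]
        peaks = vol.z_axis[np.argmax(np.abs(vol.data), axis=2)]
        assert np.all(np.abs(peaks - z0) <= dz)

    def test_zero_padding_refines_sampling_not_position(self, spectral_config):
        st = _mirror_stack(spectral_config, 150.0)
        v1 = reconstruct_depth(st, pad_factor=1)
        v2 = reconstruct_depth(st, pad_factor=2)
        dz1 = v1.z_axis[1] - v1.z_axis[0]
        dz2 = v2.z_axis[1] - v2.z_axis[0]
        assert dz2 == pytest.approx(dz1 / 2)
        p1 = v1.z_axis[np.argmax(np.abs(v1.data[0, 0]))]
        p2 = v2.z_axis[np.argmax(np.abs(v2.data[0, 0]))]
        assert abs(p1 - p2) <= dz1 / 2 + 1e-9

    def test_real_input_spectrum_is_hermitian(self, spectral_config):
        # discarding the negative-frequency half loses nothing for real data
        st = _mirror_stack(spectral_config, 150.0)
        x = st.data[4, 4]
        spec = np.fft.fft(x)
        mirror = np.conj(spec[::-1])
        mirror = np.roll(mirror, 1)
        assert np.allclose(spec, mirror, atol=1e-9 * np.abs(spec).max())

    def test_matches_direct_fourier_sum_oracle(self):
        # 8×8×32 stack on a uniform k axis vs an explicit DFT loop
        rng = np.random.default_rng(5)
        data = rng.random((8, 8, 32))
        k = np.linspace(7.2, 7.9, 32)
        st = SpectralStack(data, k, dc_removed=True)
        vol = reconstruct_depth(st, pad_factor=2)
        n_pad = 64
        for y, x in [(0, 0), (3, 5), (7, 7)]:
            oracle = np.zeros(n_pad, complex)
            for n in range(n_pad):
                acc = 0.0 + 0.0j
                for l in range(32):
                    acc += data[y, x, l] * np.exp(-2j * np.pi * l * n / n_pad)
                oracle[n] = np.conj(acc)
            assert np.allclose(vol.data[y, x], oracle[:32],
                               atol=1e-9 * np.abs(oracle).max())

    def test_nonuniform_k_resampled(self, spectral_config):
        st = _mirror_stack(spectral_config, 150.0)
        vol = reconstruct_depth(st, pad_factor=1)
        assert vol.provenance[0]["resampled_uniform_k"] is True

    def test_nonmonotonic_k_rejected(self):
        k = np.array([7.2, 7.5, 7.4, 7.9])
        with pytest.raises(ValueError):
            SpectralStack(np.zeros((8, 8, 4)), k)

    def test_invalid_pad_factor_rejected(self, spectral_config):
        st = _mirror_stack(spectral_config, 150.0)
        with pytest.raises(ValueError):
            reconstruct_depth(st, pad_factor=0)

    def test_provenance_records_stages(self, spectral_config):
        vol = reconstruct_depth(_mirror_stack(spectral_config, 150.0), pad_factor=2)
        assert vol.provenance[0]["stage"] == "reconstruct_depth"
        assert vol.provenance[0]["pad_factor"] == 2


class TestAttenuationFit:
    def test_recovers_known_mu_without_crosstalk(self, spectral_config):
        mu = 3e-3
        ph = make_phantom("two_layer_slab_with_defect", spectral_config, mu1=mu,
                          mu2=6e-3, t1=200.0, t2=200.0, z_top=50.0,
                          defect_radius=0.0, crosstalk_strength=0.0,
                          r1=0.01, r2=0.01)
        flat = generate_phase_mask(spectral_config, "flat", 0)
        st = remove_dc(simulate_stack(ph, spectral_config, flat, crosstalk=False),
                       "mean_subtract")
        vol = reconstruct_depth(st, pad_factor=2)
        fit = fit_attenuation_profile(vol, (70.0, 230.0))
        assert fit["mu"] == pytest.approx(mu, rel=0.10)


class TestFixedPattern:
    def test_no_false_positives_on_clean_volumes(self):
        # null simulation over several seeds: < 0.1% flagged bins
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vol = rng.random((32, 32, 8))
            filt = estimate_fixed_pattern_filter(vol)
            assert filt.n_notched <= 0.001 * 32 * 32

    def test_injected_tone_flagged_with_mirror(self):
        rng = np.random.default_rng(0)
        vol = rng.random((32, 32, 8))
        yy, xx = np.mgrid[0:32, 0:32]
        vol += np.cos(2 * np.pi * (5 * xx + 3 * yy) / 32)[:, :, None]
        filt = estimate_fixed_pattern_filter(vol)
        assert filt.notch_mask[3, 5]
        assert filt.notch_mask[-3, -5]

    def test_point_symmetry_enforced(self):
        rng = np.random.default_rng(1)
        vol = rng.random((32, 32, 8))
        yy, xx = np.mgrid[0:32, 0:32]
        vol += np.cos(2 * np.pi * (7 * xx) / 32)[:, :, None]
        filt = estimate_fixed_pattern_filter(vol)
        assert np.array_equal(filt.notch_mask, _point_reflect(filt.notch_mask))

    def test_asymmetric_mask_rejected(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2, 3] = True  # reflection (14, 13) missing
        with pytest.raises(ValueError, match="symmetric"):
            FixedPatternFilter(notch_mask=mask)

    def test_too_few_planes_rejected(self):
        with pytest.raises(ValueError):
            estimate_fixed_pattern_filter(np.zeros((16, 16, 2)))


class TestApplyFilter:
    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(2)
        vol = rng.random((16, 16, 6))
        filt = FixedPatternFilter(notch_mask=np.zeros((16, 16), dtype=bool))
        out = apply_spatial_filter(vol, filt)
        assert np.allclose(out, vol, atol=1e-12 * np.abs(vol).max())

    def test_tone_attenuated_others_preserved(self):
        rng = np.random.default_rng(3)
        vol = rng.random((32, 32, 8))
        yy, xx = np.mgrid[0:32, 0:32]
        tone = np.cos(2 * np.pi * (5 * xx + 3 * yy) / 32)
        noisy = vol + tone[:, :, None]
        filt = estimate_fixed_pattern_filter(noisy)
        out = apply_spatial_filter(noisy, filt)
        spec_out = np.abs(np.fft.fft2(out[:, :, 0]))
        spec_in = np.abs(np.fft.fft2(noisy[:, :, 0]))
        assert spec_out[3, 5] < spec_in[3, 5] * 10 ** (-60 / 20)
        untouched = ~filt.notch_mask
        assert np.allclose(spec_out[untouched], spec_in[untouched], rtol=0.01)

    def test_parseval_energy_accounting(self):
        rng = np.random.default_rng(4)
        vol = rng.random((16, 16, 4))
        mask = np.zeros((16, 16), dtype=bool)
        mask[2, 5] = mask[-2, -5] = True
        filt = FixedPatternFilter(notch_mask=mask)
        out = apply_spatial_filter(vol, filt)
        for iz in range(4):
            spec = np.fft.fft2(vol[:, :, iz])
            removed = np.sum(np.abs(spec[mask]) ** 2) / mask.size
            e_in = np.sum(vol[:, :, iz] ** 2)
            e_out = np.sum(out[:, :, iz] ** 2)
            assert e_in - e_out == pytest.approx(removed, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        filt = FixedPatternFilter(notch_mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            apply_spatial_filter(np.zeros((16, 16, 4)), filt)
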