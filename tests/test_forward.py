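"""Forward model: ballistic propagation, crosstalk statistics, detection."""

import numpy as np
import pytest

from stoct import (
    ComplexField,
    Layer,
    OpticalConfig,
    ScatteringPhantom,
    acquire_volume,
    generate_phase_mask,
    generate_mask_ensemble,
    make_phantom,
    propagate_crosstalk,
    propagate_mirror,
    record_interferogram,
    reference_field,
    simulate_stack,
)
from stoct.forward import mirror_slices


def _mirror_phantom(config, z0, reflectivity=0.25):
    shape = (config.ny, config.nx)
    return ScatteringPhantom(
        layers=(Layer(z0, 0.0, np.full(shape, reflectivity)),),
        backscatter_fraction=0.0,
    )


class TestPropagateMirror:
    def test_mirror_at_zero_depth_has_zero_phase(self, small_config, flat_mask):
        ph = _mirror_phantom(small_config, 0.0)
        k = float(small_config.k_axis[10])
        f = propagate_mirror(ph, small_config, k, flat_mask)
        assert f.component == "mirror"
        assert np.allclose(f.values, 0.5, atol=1e-10)  # √0.25, phase 0

    def test_round_trip_phase_at_depth(self, small_config, flat_mask):
        z0 = 120.0
        ph = _mirror_phantom(small_config, z0)
        k = float(small_config.k_axis[3])
        f = propagate_mirror(ph, small_config, k, flat_mask)
        expected = np.angle(np.exp(-2j * k * z0))
        assert np.allclose(np.angle(f.values), expected, atol=1e-9)

    def test_beer_lambert_two_layer_amplitude_ratio(self, small_config):
        # closed form: amp₂/amp₁ = √(r₂/r₁)·exp(−2µ₁d₁)
        shape = (small_config.ny, small_config.nx)
        r1, r2, mu1, d1 = 0.36, 0.16, 4e-3, 150.0
        ph = ScatteringPhantom(
            layers=(
                Layer(0.0, d1, np.full(shape, r1), scattering_mu=mu1),
                Layer(d1, 0.0, np.full(shape, r2)),
            ),
            backscatter_fraction=0.0,
        )
        zs, maps = mirror_slices(ph, small_config)
        expected = np.sqrt(r2 / r1) * np.exp(-2 * mu1 * d1)
        measured = abs(maps[1]).mean() / abs(maps[0]).mean()
        assert measured == pytest.approx(expected, rel=1e-9)

    def test_out_of_band_wavenumber_rejected(self, small_config, flat_mask):
        ph = _mirror_phantom(small_config, 0.0)
        with pytest.raises(ValueError, match="sweep band"):
            propagate_mirror(ph, small_config, 99.0, flat_mask)

    def test_mask_phase_applied_to_field(self, small_config):
        ph = _mirror_phantom(small_config, 0.0)
        mask = generate_phase_mask(small_config, "slm", 4)
        k = float(small_config.k_axis[0])
        f = propagate_mirror(ph, small_config, k, mask)
        assert np.allclose(np.angle(f.values), mask.phase, atol=1e-9)


class TestPropagateCrosstalk:
    def _diffuser(self, config, strength=1.0, mu=5e-3, d=100.0):
        return make_phantom("plane_behind_diffuser", config, mu=mu, thickness=d,
                            z_plane=150.0, crosstalk_strength=strength)

    def test_zero_strength_gives_zero_field(self, small_config, flat_mask):
        ph = self._diffuser(small_config, strength=0.0)
        k = float(small_config.k_axis[5])
        f = propagate_crosstalk(ph, small_config, k, flat_mask)
        assert np.all(f.values == 0)

    def test_two_masks_decorrelated(self, flat_mask):
        cfg = OpticalConfig(nx=64, ny=64, n_k=16, na_det=0.3, na_ill=0.1,
                            pixel_pitch_obj=2.0)
        ph = self._diffuser(cfg)
        k = float(cfg.k_axis[8])
        f1 = propagate_crosstalk(ph, cfg, k, generate_phase_mask(cfg, "flat", 1))
        f2 = propagate_crosstalk(ph, cfg, k, generate_phase_mask(cfg, "flat", 2))
        num = np.vdot(f1.values.ravel(), f2.values.ravel())
        den = np.sqrt(np.sum(abs(f1.values) ** 2) * np.sum(abs(f2.values) ** 2))
        assert abs(num / den) < 0.1

    def test_mean_intensity_matches_configured_variance(self):
        cfg = OpticalConfig(nx=128, ny=128, n_k=16, na_det=0.3, na_ill=0.1,
                            pixel_pitch_obj=2.0)
        mu, d, strength = 5e-3, 100.0, 1.0
        ph = self._diffuser(cfg, strength, mu, d)
        k = float(cfg.k_axis[8])
        f = propagate_crosstalk(ph, cfg, k, generate_phase_mask(cfg, "flat", 3))
        var = strength * (1 - np.exp(-2 * mu * d))
        assert np.mean(np.abs(f.values) ** 2) == pytest.approx(var, rel=0.05)

    def test_frozen_mode_constant_speckle_across_sweep(self, small_config, flat_mask):
        # single crosstalk depth: frozen speckle differs between wavenumbers
        # only by the deterministic round-trip phase
        ph = self._diffuser(small_config)
        k1, k2 = (float(small_config.k_axis[i]) for i in (0, 40))
        f1 = propagate_crosstalk(ph, small_config, k1, flat_mask, mode="frozen", n_ct=1)
        f2 = propagate_crosstalk(ph, small_config, k2, flat_mask, mode="frozen", n_ct=1)
        num = abs(np.vdot(f1.values.ravel(), f2.values.ravel()))
        den = np.sqrt(np.sum(abs(f1.values) ** 2) * np.sum(abs(f2.values) ** 2))
        assert num / den > 0.999

    def test_per_k_mode_redraws_speckle(self, small_config, flat_mask):
        ph = self._diffuser(small_config)
        k1, k2 = (float(small_config.k_axis[i]) for i in (0, 40))
        f1 = propagate_crosstalk(ph, small_config, k1, flat_mask, mode="per_k", n_ct=1)
        f2 = propagate_crosstalk(ph, small_config, k2, flat_mask, mode="per_k", n_ct=1)
        num = abs(np.vdot(f1.values.ravel(), f2.values.ravel()))
        den = np.sqrt(np.sum(abs(f1.values) ** 2) * np.sum(abs(f2.values) ** 2))
        assert num / den < 0.1


class TestFieldAdditivity:
    def test_total_equals_mirror_plus_crosstalk(self, small_config, flat_mask):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3)
        k = float(small_config.k_axis[7])
        m = propagate_mirror(ph, small_config, k, flat_mask)
        c = propagate_crosstalk(ph, small_config, k, flat_mask)
        total = m + c
        assert total.component == "total"
        assert np.array_equal(total.values, m.values + c.values)

    def test_grid_mismatch_rejected(self):
        a = ComplexField(np.zeros((8, 8), complex), 7.0, "mirror")
        b = ComplexField(np.zeros((16, 16), complex), 7.0, "crosstalk")
        with pytest.raises(ValueError):
            a + b

    def test_nonfinite_field_rejected(self):
        bad = np.full((8, 8), np.nan, dtype=complex)
        with pytest.raises(ValueError):
            ComplexField(bad, 7.0)


class TestRecordInterferogram:
    def test_zero_sample_gives_pure_reference(self, small_config, flat_mask):
        k = float(small_config.k_axis[0])
        es = ComplexField(np.zeros((small_config.ny, small_config.nx), complex), k, "total")
        er = reference_field(small_config, k, flat_mask)
        i = record_interferogram(es, er, small_config)
        assert np.allclose(i, small_config.ref_amplitude**2)

    def test_fully_constructive_interference(self, small_config, flat_mask):
        k = float(small_config.k_axis[0])
        er = reference_field(small_config, k, flat_mask)
        es = ComplexField(er.values.copy(), k, "total")
        i = record_interferogram(es, er, small_config)
        assert np.allclose(i, 4 * small_config.ref_amplitude**2)

    def test_fringe_term_is_cosine_of_round_trip_phase(self, small_config, flat_mask):
        # oracle: I − |E_s|² − |E_r|² = 2·A_MI·A_ref·cos(2kz₀) per pixel
        z0, r = 100.0, 0.25
        ph = _mirror_phantom(small_config, z0, r)
        a_mi, a_ref = np.sqrt(r), small_config.ref_amplitude
        for ki in (0, 17, 43):
            k = float(small_config.k_axis[ki])
            es = propagate_mirror(ph, small_config, k, flat_mask)
            er = reference_field(small_config, k, flat_mask)
            i = record_interferogram(es, er, small_config)
            fringe = i - np.abs(es.values) ** 2 - a_ref**2
            expected = 2 * a_mi * a_ref * np.cos(2 * k * z0)
            assert np.allclose(fringe, expected, atol=1e-9)

    def test_mirror_fringe_is_mask_invariant(self, small_config):
        # the mask phase enters both arms and cancels in the intensity
        ph = _mirror_phantom(small_config, 80.0)
        k = float(small_config.k_axis[11])
        frames = []
        for seed in range(3):
            mask = generate_phase_mask(small_config, "slm", seed)
            es = propagate_mirror(ph, small_config, k, mask)
            er = reference_field(small_config, k, mask)
            frames.append(record_interferogram(es, er, small_config))
        assert np.allclose(frames[0], frames[1], atol=1e-9)
        assert np.allclose(frames[0], frames[2], atol=1e-9)

    def test_grid_mismatch_rejected(self, small_config, flat_mask):
        k = float(small_config.k_axis[0])
        es = ComplexField(np.zeros((8, 8), complex), k)
        er = reference_field(small_config, k, flat_mask)
        with pytest.raises(ValueError):
            record_interferogram(es, er, small_config)

    def test_shot_noise_and_quantization(self, small_config, flat_mask):
        k = float(small_config.k_axis[0])
        er = reference_field(small_config, k, flat_mask)
        es = ComplexField(0.1 * er.values, k, "total")
        rng = np.random.default_rng(0)
        noisy = record_interferogram(es, er, small_config, shot_noise=True, rng=rng)
        clean = record_interferogram(es, er, small_config)
        assert not np.array_equal(noisy, clean)
        assert noisy.mean() == pytest.approx(clean.mean(), rel=0.01)
        quant = record_interferogram(es, er, small_config, quantize=True)
        levels = np.unique(np.round(quant / quant.max() * (2**small_config.bit_depth - 1)))
        assert levels.size <= 2**small_config.bit_depth


class TestAcquireVolume:
    def test_single_flat_mask_modes_agree(self, small_config, flat_mask):
        ph = _mirror_phantom(small_config, 100.0)
        seq = acquire_volume(ph, small_config, [flat_mask], mode="sequential")
        integ = acquire_volume(ph, small_config, [flat_mask], mode="camera_integrated")
        assert np.allclose(seq[0].data, integ[0].data)

    def test_camera_integration_is_arithmetic_mean(self, small_config):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3)
        masks = generate_mask_ensemble(small_config, "slm", 4, seed=1)
        seq = acquire_volume(ph, small_config, masks, mode="sequential")
        integ = acquire_volume(ph, small_config, masks, mode="camera_integrated")
        oracle = np.mean([s.data for s in seq], axis=0)
        assert np.allclose(integ[0].data, oracle, atol=1e-12)
        assert integ[0].mask_id == "integrated"

    def test_empty_mask_list_rejected(self, small_config):
        ph = _mirror_phantom(small_config, 100.0)
        with pytest.raises(ValueError):
            acquire_volume(ph, small_config, [])

    def test_determinism_bit_identical(self, small_config):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3, seed=3)
        masks = generate_mask_ensemble(small_config, "membrane", 2, seed=3,
                                       correlation_length=4.0)
        a = acquire_volume(ph, small_config, masks, rng_key=3)
        b = acquire_volume(ph, small_config, masks, rng_key=3)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.data, sb.data)

    def test_stack_matches_per_wavenumber_operations(self, small_config):
        # the vectorised sweep equals propagate + record frame by frame
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3)
        mask = generate_phase_mask(small_config, "slm", 9)
        stack = simulate_stack(ph, small_config, mask, n_ct=16)
        for ki in (0, 31, 63):
            k = float(small_config.k_axis[ki])
            es = propagate_mirror(ph, small_config, k, mask) + propagate_crosstalk(
                ph, small_config, k, mask, n_ct=16)
            er = reference_field(small_config, k, mask)
            frame = record_interferogram(es, er, small_config)
            assert np.allclose(stack.data[:, :, ki], frame, rtol=1e-10, atol=1e-10)

    def test_sweep_duration_matches_printed_timing(self):
        cfg = OpticalConfig(lambda_start=800.0, lambda_end=875.0, sweep_rate=8700.0)
        assert round(cfg.sweep_duration_ms, 1) == 8.6
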