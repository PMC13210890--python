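"""Mask-ensemble averaging, DC removal and crosstalk-suppression metrics."""

import numpy as np
import pytest

from stoct import (
    SpectralStack,
    average_stacks,
    crosstalk_residual,
    generate_mask_ensemble,
    make_phantom,
    remove_dc,
    simulate_stack,
    suppression_metrics,
)
from stoct.stoc import fringe_band_rms


def _stack(data, k=None):
    n_k = data.shape[2]
    if k is None:
        k = np.linspace(7.9, 7.2, n_k)
    return SpectralStack(data, k, dc_removed=True)


class TestAverageStacks:
    def test_single_stack_unchanged(self, small_config, flat_mask):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=0.0)
        s = simulate_stack(ph, small_config, flat_mask)
        avg = average_stacks([s])
        assert np.array_equal(avg.data, s.data)

    def test_identical_stacks_average_to_themselves(self):
        rng = np.random.default_rng(0)
        s = _stack(rng.random((8, 8, 16)))
        avg = average_stacks([s, s, s])
        assert np.allclose(avg.data, s.data)
        assert avg.mask_id == "integrated"

    def test_mismatched_k_axis_rejected(self):
        a = _stack(np.zeros((8, 8, 16)))
        b = _stack(np.zeros((8, 8, 16)), k=np.linspace(8.0, 7.0, 16))
        with pytest.raises(ValueError, match="k ax"):
            average_stacks([a, b])

    def test_commutes_with_mean_subtract(self, small_config):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3)
        masks = generate_mask_ensemble(small_config, "slm", 3, seed=4)
        stacks = [simulate_stack(ph, small_config, m) for m in masks]
        a = remove_dc(average_stacks(stacks), "mean_subtract")
        b = average_stacks([remove_dc(s, "mean_subtract") for s in stacks])
        assert np.allclose(a.data, b.data, atol=1e-12)


class TestRemoveDC:
    def test_constant_stack_zeroed(self):
        s = _stack(5.0 * np.ones((4, 4, 32)))
        out = remove_dc(s, "mean_subtract")
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_pure_cosine_preserved_by_mean_subtract(self):
        fringe = np.cos(2 * np.pi * 8 * np.arange(64) / 64)
        s = _stack(np.tile(fringe, (4, 4, 1)) + 2.0)
        out = remove_dc(s, "mean_subtract")
        assert np.allclose(out.data[0, 0], fringe, atol=1e-12)

    def test_highpass_suppresses_offset_keeps_fringe(self):
        # integer-cycle fringe at 0.25 cyc/sample, offset 6
        n_k = 256
        fringe = np.cos(2 * np.pi * 64 * np.arange(n_k) / n_k)
        s = _stack(np.tile(fringe + 6.0, (4, 4, 1)), k=np.linspace(7.9, 7.2, n_k))
        out = remove_dc(s, "highpass")
        dc_resid = abs(out.data.mean(axis=2)).max()
        assert dc_resid < 6.0 * 10 ** (-40 / 20)  # > 40 dB suppression
        amp = 2 * np.abs(np.fft.rfft(out.data[0, 0]) / n_k)[64]
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_mean_near_zero_after_mean_subtract(self, small_config, flat_mask):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=0.0)
        s = simulate_stack(ph, small_config, flat_mask)
        out = remove_dc(s, "mean_subtract")
        rms = np.sqrt(np.mean(s.data**2))
        assert np.abs(out.data.mean(axis=2)).max() < 1e-9 * rms

    def test_invalid_cutoff_rejected(self):
        s = _stack(np.ones((4, 4, 32)))
        with pytest.raises(ValueError):
            remove_dc(s, "highpass", cutoff_fraction=0.7)
        with pytest.raises(ValueError):
            remove_dc(s, "unknown")


class TestSuppression:
    def _sim(self, config, n_masks, seed=0):
        ph = make_phantom("plane_behind_diffuser", config, mu=5e-3, thickness=100.0,
                          z_plane=150.0, crosstalk_strength=1.0)
        masks = generate_mask_ensemble(config, "slm", n_masks, seed=seed)
        stacks = [simulate_stack(ph, config, m, n_ct=8, rng_key=seed) for m in masks]
        mirror_only = simulate_stack(ph, config, masks[0], crosstalk=False)
        return stacks, mirror_only

    def test_single_mask_factor_is_exactly_one(self, small_config):
        stacks, mirror = self._sim(small_config, 1)
        ct = crosstalk_residual(stacks[0], mirror)
        rep = suppression_metrics(average_stacks(stacks), mirror, ct, n_masks=1)
        assert rep.suppression_factor == pytest.approx(1.0, abs=1e-12)

    def test_zero_crosstalk_zero_residual(self, small_config, flat_mask):
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3,
                          crosstalk_strength=0.0)
        s = simulate_stack(ph, small_config, flat_mask)
        mirror = simulate_stack(ph, small_config, flat_mask, crosstalk=False)
        ct = crosstalk_residual(s, mirror)
        rep = suppression_metrics(s, mirror, ct)
        assert rep.residual_crosstalk_rms == 0.0

    def test_mirror_fringe_preserved_by_averaging(self, small_config):
        # crosstalk off: every mask yields the identical interferogram
        ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3,
                          crosstalk_strength=0.0)
        masks = generate_mask_ensemble(small_config, "slm", 8, seed=2)
        stacks = [simulate_stack(ph, small_config, m) for m in masks]
        before = fringe_band_rms(stacks[0])
        after = fringe_band_rms(average_stacks(stacks))
        assert abs(after - before) / before < 1e-6

    def test_residual_rms_scales_as_inverse_sqrt_masks(self, small_config):
        # Monte-Carlo over replicates: fitted log-log slope −0.5 ± 0.05
        slopes = []
        ms = [4, 16, 64]
        for rep in range(6):
            ph = make_phantom("plane_behind_diffuser", small_config, mu=5e-3,
                              thickness=100.0, z_plane=150.0, crosstalk_strength=1.0)
            masks = generate_mask_ensemble(small_config, "slm", max(ms), seed=30 + rep)
            stacks = [simulate_stack(ph, small_config, m, mirror=False, n_ct=8,
                                     rng_key=rep) for m in masks]
            rms = [fringe_band_rms(average_stacks(stacks[:m])) for m in ms]
            slopes.append(np.polyfit(np.log(ms), np.log(rms), 1)[0])
        assert np.mean(slopes) == pytest.approx(-0.5, abs=0.05)
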