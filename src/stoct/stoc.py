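"""STOC crosstalk suppression: mask-ensemble averaging of interferograms,
DC removal, and residual-crosstalk metrics.

Averaging interferograms recorded under N uncorrelated phase masks leaves
the ballistic (mirror) fringe untouched — its mask phase cancels between
the two interferometer arms — while the crosstalk terms, whose phases are
uncorrelated across masks, average toward zero with the usual √N law.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .forward import SpectralStack

DEFAULT_CUTOFF = 0.02  # fraction of the Nyquist fringe frequency


@dataclasses.dataclass(frozen=True)
class AveragingReport:
    """Summary of one mask-averaging experiment."""

    n_masks: int
    residual_crosstalk_rms: float
    mirror_fringe_amplitude: float
    suppression_factor: float


def _check_compatible(stacks: list[SpectralStack]) -> None:
    ref = stacks[0]
    for s in stacks[1:]:
        if s.data.shape != ref.data.shape:
            raise ValueError("stacks have mismatched grids")
        if not np.allclose(s.k_axis, ref.k_axis, rtol=0, atol=1e-12):
            raise ValueError("stacks have mismatched k axes")


def average_stacks(stacks: list[SpectralStack]) -> SpectralStack:
    """Elementwise arithmetic mean over the mask ensemble."""
    if not stacks:
        raise ValueError("need at least one stack")
    _check_compatible(stacks)
    mean = np.mean([s.data for s in stacks], axis=0)
    return SpectralStack(
        mean,
        stacks[0].k_axis,
        mask_id="integrated",
        acquisition_mode="camera_integrated",
        dc_removed=any(s.dc_removed for s in stacks),
    )


def remove_dc(
    stack: SpectralStack,
    method: str = "mean_subtract",
    cutoff_fraction: float = DEFAULT_CUTOFF,
) -> SpectralStack:
    """Remove the per-pixel DC component of the spectral fringe.

    ``mean_subtract`` subtracts each pixel's mean along k.  ``highpass``
    applies a zero-phase Gaussian high-pass whose half-amplitude point sits
    at ``cutoff_fraction`` of the Nyquist fringe frequency.
    """
    if method == "mean_subtract":
        out = stack.data - stack.data.mean(axis=2, keepdims=True)
    elif method == "highpass":
        if stack.data.shape[2] < 4:
            raise ValueError("highpass needs n_k >= 4")
        if not (0 < cutoff_fraction < 0.5):
            raise ValueError("cutoff_fraction must lie in (0, 0.5)")
        n_k = stack.data.shape[2]
        f = np.fft.rfftfreq(n_k)  # cycles/sample, Nyquist = 0.5
        f_c = cutoff_fraction * 0.5
        sigma = f_c / np.sqrt(2.0 * np.log(2.0))
        h = 1.0 - np.exp(-(f**2) / (2.0 * sigma**2))
        spec = np.fft.rfft(stack.data, axis=2) * h
        out = np.fft.irfft(spec, n=n_k, axis=2)
    else:
        raise ValueError(f"unknown DC-removal method {method!r}")
    return SpectralStack(out, stack.k_axis, stack.mask_id, stack.acquisition_mode,
                         dc_removed=True)


def fringe_band_rms(
    data_or_stack, cutoff_fraction: float = DEFAULT_CUTOFF
) -> float:
    """RMS of the interferometric fringe band: spectral content at
    |fringe frequency| > cutoff_fraction × Nyquist, per pixel along k."""
    data = data_or_stack.data if isinstance(data_or_stack, SpectralStack) else np.asarray(data_or_stack)
    n_k = data.shape[-1]
    f = np.fft.rfftfreq(n_k)
    keep = f > cutoff_fraction * 0.5
    spec = np.fft.rfft(data, axis=-1) * keep
    band = np.fft.irfft(spec, n=n_k, axis=-1)
    return float(np.sqrt(np.mean(band**2)))


def suppression_metrics(
    avg: SpectralStack,
    mirror_only: SpectralStack,
    crosstalk_only: SpectralStack,
    n_masks: int = 1,
    cutoff_fraction: float = DEFAULT_CUTOFF,
) -> AveragingReport:
    """Residual-crosstalk metrics from matched simulations.

    ``mirror_only`` is the crosstalk-free acquisition; ``crosstalk_only`` is
    the single-mask crosstalk residual, i.e. one total stack minus
    ``mirror_only`` (see :func:`crosstalk_residual`), which serves as the
    "before averaging" reference.  The suppression factor is the
    fringe-band RMS of that reference divided by the fringe-band RMS of
    ``avg − mirror_only``.
    """
    for s in (mirror_only, crosstalk_only):
        if s.data.shape != avg.data.shape:
            raise ValueError("stacks have mismatched grids")
    mirror_amp = np.sqrt(2.0) * fringe_band_rms(mirror_only, cutoff_fraction)
    residual = avg.data - mirror_only.data
    after = fringe_band_rms(residual, cutoff_fraction)
    before = fringe_band_rms(crosstalk_only, cutoff_fraction)
    factor = np.inf if after == 0 else before / after
    if before == 0:
        factor = 1.0 if after == 0 else 0.0
    return AveragingReport(
        n_masks=n_masks,
        residual_crosstalk_rms=after,
        mirror_fringe_amplitude=mirror_amp,
        suppression_factor=float(factor),
    )


def crosstalk_residual(total: SpectralStack, mirror_only: SpectralStack) -> SpectralStack:
    """Difference stack total − mirror: the crosstalk contribution to the
    recorded intensity of one exposure."""
    if total.data.shape != mirror_only.data.shape:
        raise ValueError("stacks have mismatched grids")
    return SpectralStack(
        total.data - mirror_only.data, total.k_axis, total.mask_id,
        total.acquisition_mode, dc_removed=True,
    )
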