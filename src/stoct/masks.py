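"""Spatial phase mask generation.

A STOC acquisition records interferograms under a sequence of mutually
uncorrelated 2-D phase patterns Δφ(x, y) imposed on the illumination.
Three physical modulators are emulated — a pixelated SLM, a deformable
membrane, and the modal speckle of a long multimode fiber — plus a flat
(unmodulated) reference case.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .config import OpticalConfig

MASK_KINDS = ("slm", "membrane", "fiber_modes", "flat")


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    out = np.mod(-phi + np.pi, 2.0 * np.pi)
    return np.pi - out


@dataclasses.dataclass(frozen=True)
class PhaseMask:
    """One realization of the illumination phase pattern Δφ(x, y).

    ``phase`` is wrapped to (−π, π].  ``seed`` identifies the realization;
    two masks of the same kind with different seeds are statistically
    uncorrelated (ensemble correlation modulus < 0.1 over the pixel
    population).  A ``flat`` mask has zero phase but still carries a seed,
    which downstream code uses to seed the crosstalk speckle realization
    associated with that exposure.
    """

    phase: np.ndarray
    kind: str
    seed: int
    correlation_length: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")
        p = np.asarray(self.phase, dtype=float)
        if p.ndim != 2:
            raise ValueError("phase must be a 2-D array")
        if np.any(p > np.pi + 1e-12) or np.any(p <= -np.pi - 1e-12):
            raise ValueError("phase must be wrapped to (-pi, pi]")
        if self.kind == "flat" and np.any(p != 0):
            raise ValueError("flat mask must have zero phase")

    @property
    def modulation(self) -> np.ndarray:
        """The complex factor e^{iΔφ}."""
        return np.exp(1j * self.phase)


def mask_correlation(a: PhaseMask, b: PhaseMask) -> complex:
    """Ensemble correlation ⟨e^{iΔφ_a} e^{−iΔφ_b}⟩ over the pixel population."""
    return complex(np.mean(np.exp(1j * (a.phase - b.phase))))


def generate_phase_mask(
    config: OpticalConfig,
    kind: str,
    seed: int,
    correlation_length: float = 1.0,
    n_modes: int | None = None,
    peak_to_valley: float = 6.0 * np.pi,
) -> PhaseMask:
    """Generate one phase-mask realization on the detector grid.

    slm         : piecewise-constant tiles of side ``correlation_length``
                  pixels, uniform phases on (−π, π].
    membrane    : smooth Gaussian random surface, low-pass filtered at
                  ``correlation_length`` pixels and scaled to the requested
                  peak-to-valley (default 6π, i.e. several wraps) before
                  wrapping.
    fiber_modes : random superposition of ``n_modes`` orthogonal speckle
                  patterns with uniform random modal phases; the phase of
                  the resulting complex field is the mask.
    flat        : zeros (spatially coherent illumination).

    Deterministic for a fixed seed.
    """
    if kind not in MASK_KINDS:
        raise ValueError(f"unknown mask kind {kind!r}")
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1 pixel")
    if correlation_length > min(config.nx, config.ny):
        raise ValueError("correlation_length exceeds the grid")
    ny, nx = config.ny, config.nx
    rng = np.random.default_rng(np.random.SeedSequence([0x5705C, abs(int(seed)), MASK_KINDS.index(kind)]))

    if kind == "flat":
        phase = np.zeros((ny, nx))
    elif kind == "slm":
        tile = max(1, int(round(correlation_length)))
        th, tw = -(-ny // tile), -(-nx // tile)
        tiles = rng.uniform(-np.pi, np.pi, size=(th, tw))
        phase = np.kron(tiles, np.ones((tile, tile)))[:ny, :nx]
        phase = _wrap_phase(phase)
    elif kind == "membrane":
        field = rng.standard_normal((ny, nx))
        field = ndimage.gaussian_filter(field, sigma=correlation_length, mode="wrap")
        pv = field.max() - field.min()
        if pv > 0:
            field *= peak_to_valley / pv
        phase = _wrap_phase(field)
    else:  # fiber_modes
        if n_modes is None:
            raise ValueError("fiber_modes requires n_modes")
        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        npix = ny * nx
        m = min(n_modes, npix)
        # orthonormal speckle basis shared by all seeds of this grid, random
        # modal phases per realization (mode excitation along the fiber)
        basis_rng = np.random.default_rng(np.random.SeedSequence([0xF1BE5, ny, nx, m]))
        g = basis_rng.standard_normal((npix, m)) + 1j * basis_rng.standard_normal((npix, m))
        q, _ = np.linalg.qr(g)
        modal_phases = rng.uniform(-np.pi, np.pi, size=m)
        field = (q @ np.exp(1j * modal_phases)).reshape(ny, nx)
        phase = np.angle(field)
        phase[phase <= -np.pi] = np.pi
    return PhaseMask(phase=phase, kind=kind, seed=int(seed), correlation_length=float(correlation_length))


def generate_mask_ensemble(
    config: OpticalConfig,
    kind: str,
    n_masks: int,
    seed: int = 0,
    correlation_length: float = 1.0,
    **kwargs,
) -> list[PhaseMask]:
    """Generate ``n_masks`` uncorrelated masks with seeds derived from ``seed``."""
    if n_masks < 1:
        raise ValueError("n_masks must be >= 1")
    base = int(seed) * 1_000_003
    return [
        generate_phase_mask(config, kind, base + i, correlation_length, **kwargs)
        for i in range(n_masks)
    ]
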