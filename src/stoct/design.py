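"""Closed-form design calculators for multimode-fiber illumination and
swept-source acquisition budgets.

These are the back-of-envelope numbers that size a STOC-T system: how many
spatial modes a step-index multimode fiber supports (each mode acts as one
independent phase pattern), the resulting √N crosstalk attenuation, the
illumination depth of field, the minimum fiber length needed for modal
delays to exceed the source coherence time, and acquisition timing /
dataset sizing.
"""

from __future__ import annotations

import dataclasses
import math

from .config import OpticalConfig


@dataclasses.dataclass(frozen=True)
class FiberSpec:
    """Step-index multimode fiber used as a passive spatial-phase scrambler.

    core_radius : core radius a, µm
    na : numerical aperture (dimensionless, < core_index)
    wavelength : operating wavelength λ, nm
    core_index : core refractive index n1 (needed for min_fiber_length)
    coherence_length : source coherence length l_c, mm (for min_fiber_length)
    length : physical fiber length, m (informational)
    """

    core_radius: float
    na: float
    wavelength: float
    core_index: float | None = None
    coherence_length: float | None = None
    length: float | None = None

    def __post_init__(self) -> None:
        if self.core_radius <= 0 or self.na <= 0 or self.wavelength <= 0:
            raise ValueError("core_radius, na and wavelength must be positive")
        if self.core_index is not None and not (self.na < self.core_index):
            raise ValueError("numerical aperture must be smaller than core index")


def guided_mode_count(fiber: FiberSpec) -> tuple[float, int]:
    """Number of guided transverse modes N ≈ 2π²a²NA²/λ².

    Returns the real-valued estimate and its nearest integer.  Both
    polarisations are counted (factor 2).
    """
    a_um = fiber.core_radius
    lam_um = fiber.wavelength * 1e-3
    if lam_um <= 0:
        raise ValueError("wavelength must be positive")
    n = 2.0 * math.pi**2 * a_um**2 * fiber.na**2 / lam_um**2
    return n, round(n)


def crosstalk_attenuation_factor(n_modes: float) -> float:
    """Expected crosstalk-noise attenuation √N for N independent modes/masks."""
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    return math.sqrt(n_modes)


def depth_of_field(wavelength_nm: float, na_ill: float, prefactor: float = 1.0) -> float:
    """Illumination depth of field DOF = prefactor · λ / NA_ill², in µm.

    Only the proportionality λ/NA² is physically fixed; the prefactor
    depends on the sharpness criterion and defaults to 1.
    """
    if na_ill <= 0:
        raise ValueError("na_ill must be positive")
    return prefactor * wavelength_nm * 1e-3 / na_ill**2


def min_fiber_length(fiber: FiberSpec) -> float:
    """Minimum fiber length L_min = 4·l_c·π²·a²·n1/λ² (metres).

    This is the length at which the maximum intermodal group delay exceeds
    the source coherence time, so that the guided modes become mutually
    incoherent.  Requires ``core_index`` and ``coherence_length`` to be set.
    """
    if fiber.core_index is None or fiber.coherence_length is None:
        raise ValueError("min_fiber_length requires core_index and coherence_length")
    a_m = fiber.core_radius * 1e-6
    lam_m = fiber.wavelength * 1e-9
    lc_m = fiber.coherence_length * 1e-3
    return 4.0 * lc_m * math.pi**2 * a_m**2 * fiber.core_index / lam_m**2


def sweep_timing(config: OpticalConfig, n_volumes: int, bytes_per_voxel: int = 2) -> dict:
    """Acquisition timing and raw dataset size for ``n_volumes`` sweeps.

    per_volume_ms : sweep band / sweep rate
    total_ms      : n volumes plus (n-1) idle periods
    data_gb       : decimal GB (1e9 bytes); default 2 B/voxel, i.e. 12-bit
                    samples stored in a 16-bit container.
    """
    if config.sweep_rate <= 0:
        raise ValueError("sweep_rate must be positive")
    per_volume = config.sweep_duration_ms
    if n_volumes <= 0:
        return {"per_volume_ms": per_volume, "total_ms": 0.0, "data_gb": 0.0}
    total = n_volumes * per_volume + (n_volumes - 1) * config.idle_time
    voxels = n_volumes * config.nx * config.ny * config.n_k
    return {
        "per_volume_ms": per_volume,
        "total_ms": total,
        "data_gb": voxels * bytes_per_voxel / 1e9,
    }
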