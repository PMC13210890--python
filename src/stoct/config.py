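"""Optical system configuration for full-field swept-source acquisition.

The configuration mirrors a swept-source full-field interferometric setup:
a tunable laser sweeping ``lambda_start`` → ``lambda_end`` while a camera
records 2-D interferograms at ``n_k`` wavelength samples.  All lateral
distances are in object-space micrometres; wavelengths in nanometres;
wavenumbers in rad/µm.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np


@dataclasses.dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the swept-source full-field interferometer.

    Parameters
    ----------
    lambda_start, lambda_end : float
        Sweep band edges in nm (``lambda_end > lambda_start > 0``).
    n_k : int
        Number of spectral frames recorded across the sweep (>= 2).
    sweep_rate : float
        Laser tuning speed in nm/s.
    idle_time : float
        Dead time between successive volume sweeps, ms.
    frame_rate : float
        Camera frame rate, Hz.
    nx, ny : int
        Detector pixel counts (>= 8 each).
    pixel_pitch_obj : float
        Object-space sampling, µm/pixel.
    na_ill, na_det : float
        Illumination and detection numerical apertures,
        ``0 < na_ill <= na_det < 1``.
    ref_amplitude : float
        Reference-arm field amplitude (arbitrary units).
    bit_depth : int
        Camera quantisation depth in bits.
    focus_z : float
        Depth of the focal plane, µm.  Scatterers away from this depth
        acquire a paraxial defocus pupil phase; ``None`` disables defocus
        modelling (everything in focus).
    """

    lambda_start: float = 800.0
    lambda_end: float = 875.0
    n_k: int = 512
    sweep_rate: float = 8700.0
    idle_time: float = 0.3
    frame_rate: float = 60000.0
    nx: int = 512
    ny: int = 512
    pixel_pitch_obj: float = 2.0
    na_ill: float = 0.1
    na_det: float = 0.2
    ref_amplitude: float = 10.0
    bit_depth: int = 12
    focus_z: float | None = None

    def __post_init__(self) -> None:
        if not (self.lambda_end > self.lambda_start > 0):
            raise ValueError("require lambda_end > lambda_start > 0")
        if self.n_k < 2:
            raise ValueError("n_k must be >= 2")
        if self.nx < 8 or self.ny < 8:
            raise ValueError("nx, ny must be >= 8")
        if not (0 < self.na_ill <= self.na_det < 1):
            raise ValueError("require 0 < na_ill <= na_det < 1")
        if self.pixel_pitch_obj <= 0:
            raise ValueError("pixel_pitch_obj must be positive")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        """Wavelength samples, uniform in λ as swept lasers tune (nm)."""
        return np.linspace(self.lambda_start, self.lambda_end, self.n_k)

    @property
    def k_axis(self) -> np.ndarray:
        """Wavenumber samples k_l = 2π/λ_l in rad/µm (strictly decreasing)."""
        lam_um = self.wavelengths_nm * 1e-3
        return 2.0 * np.pi / lam_um

    @property
    def center_wavelength_nm(self) -> float:
        return 0.5 * (self.lambda_start + self.lambda_end)

    @property
    def sweep_duration_ms(self) -> float:
        """Single-volume sweep time, ms."""
        return (self.lambda_end - self.lambda_start) / self.sweep_rate * 1e3

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "OpticalConfig":
        return cls(**json.loads(s))
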