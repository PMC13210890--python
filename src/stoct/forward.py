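"""Forward model of full-field swept-source interferometric acquisition.

The detected sample field is split into two additive components:

* a **mirror** (ballistic) component that maps object points one-to-one
  onto detector pixels — a coherent sum over discrete axial scatterers
  ``A_j(x, y) · exp(−2τ_j) · exp(−i 2 k z_j)``, where τ_j is the single-pass
  optical depth above the scatterer and 2kz the round-trip phase;
* a **crosstalk** component representing multiply scattered light that has
  lost its spatial registration.  It is modelled statistically as circular
  complex Gaussian speckle, low-pass filtered to the detection aperture,
  with total variance equal to ``crosstalk_strength × (1 − exp(−2µd))``
  (the ballistic energy removed by each scattering layer) distributed over
  depths from the layer top to the phantom's axial extent.

Both components, and the reference field, carry the illumination phase-mask
factor e^{iΔφ(x,y)} (the mask sits before the beam splitter, so the two
arms share it).  In the recorded intensity the mask phase therefore cancels
from the mirror fringe — the cancellation that makes mask-ensemble
averaging preserve the ballistic image — while crosstalk, whose realization
changes from mask to mask, averages away.

The detection aperture is applied as a hard circular low-pass in the 2-D
spatial-frequency plane at the centre wavelength (achromatic-aperture
approximation), to the object structure before the mask phase is attached:
the mask plane is treated as conjugate to the detector, which keeps the
mask-phase cancellation of the mirror fringe exact.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import OpticalConfig
from .masks import PhaseMask
from .phantom import ScatteringPhantom

_CT_STREAM = 0xC705A1C  # crosstalk seed-stream tag

COMPONENTS = ("mirror", "crosstalk", "total", "reference")


@dataclasses.dataclass(frozen=True)
class ComplexField:
    """A monochromatic 2-D complex field at wavenumber ``k`` (rad/µm)."""

    values: np.ndarray
    k: float
    component: str = "total"

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("field values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("field contains non-finite values")

    def __add__(self, other: "ComplexField") -> "ComplexField":
        if self.values.shape != other.values.shape:
            raise ValueError("field grids do not match")
        if self.k != other.k:
            raise ValueError("fields at different wavenumbers")
        return ComplexField(self.values + other.values, self.k, "total")


@dataclasses.dataclass(frozen=True)
class SpectralStack:
    """Real-valued interferogram stack I(y, x; k_l) for one mask (or one
    camera-integrated exposure), with its wavenumber axis in rad/µm."""

    data: np.ndarray
    k_axis: np.ndarray
    mask_id: int | str = 0
    acquisition_mode: str = "sequential"
    dc_removed: bool = False  # signed data allowed after DC removal / differencing

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        k = np.asarray(self.k_axis, dtype=float)
        if d.ndim != 3:
            raise ValueError("data must be 3-D (ny, nx, n_k)")
        if not self.dc_removed and np.any(d < 0):
            raise ValueError("intensities must be non-negative")
        if k.ndim != 1 or k.size != d.shape[2]:
            raise ValueError("k_axis length must equal n_k")
        dk = np.diff(k)
        if not (np.all(dk > 0) or np.all(dk < 0)):
            raise ValueError("k_axis must be strictly monotonic")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# pupil / aperture
# ---------------------------------------------------------------------------

def _freq_radius_sq(shape: tuple[int, int], pitch: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    return fy[:, None] ** 2 + fx[None, :] ** 2


def pupil_transfer(
    config: OpticalConfig, shape: tuple[int, int], defocus_um: float = 0.0
) -> np.ndarray:
    """Detection-aperture transfer function on the FFT frequency grid.

    Hard circular aperture of radius NA_det/λ_c (cycles/µm); a scatterer
    displaced ``defocus_um`` from the focal plane adds the paraxial defocus
    phase k_c·Δz·NA²ρ²/2 across the pupil.
    """
    lam_um = config.center_wavelength_nm * 1e-3
    f_cut = config.na_det / lam_um
    r2 = _freq_radius_sq(shape, config.pixel_pitch_obj)
    inside = r2 <= f_cut**2
    if defocus_um == 0.0:
        return inside.astype(complex)
    k_c = 2.0 * np.pi / lam_um
    rho2 = np.where(inside, r2 / f_cut**2, 0.0)
    phase = 0.5 * k_c * defocus_um * config.na_det**2 * rho2
    return np.where(inside, np.exp(1j * phase), 0.0)


def _apply_pupil(field: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(field) * transfer)


def aperture_pass_fraction(config: OpticalConfig, shape: tuple[int, int]) -> float:
    """Fraction of frequency bins inside the detection aperture."""
    lam_um = config.center_wavelength_nm * 1e-3
    f_cut = config.na_det / lam_um
    inside = _freq_radius_sq(shape, config.pixel_pitch_obj) <= f_cut**2
    return inside.mean()


# ---------------------------------------------------------------------------
# mirror (ballistic) channel
# ---------------------------------------------------------------------------

def mirror_slices(
    phantom: ScatteringPhantom, config: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Aperture-filtered, attenuated slice amplitude maps.

    Returns ``(z, maps)`` with ``z`` shape (n_slices,) and ``maps`` shape
    (n_slices, ny, nx) complex.  Map ``j`` already includes the round-trip
    amplitude attenuation exp(−2 τ_j) and, when ``config.focus_z`` is set,
    the defocus pupil phase for its depth.
    """
    slices = phantom.scatterers(config)
    zs = np.array([s.z for s in slices])
    maps = np.empty((len(slices), config.ny, config.nx), dtype=complex)
    for j, s in enumerate(slices):
        atten = np.exp(-2.0 * phantom.optical_depth(s.z))
        defocus = 0.0 if config.focus_z is None else s.z - config.focus_z
        transfer = pupil_transfer(config, s.amplitude.shape, defocus)
        maps[j] = _apply_pupil(s.amplitude * atten, transfer)
    return zs, maps


def propagate_mirror(
    phantom: ScatteringPhantom, config: OpticalConfig, k: float, mask: PhaseMask
) -> ComplexField:
    """Ballistic sample field at wavenumber ``k`` under phase mask ``mask``.

    E(x, y) = Σ_j LP[A_j e^{−2τ_j}] e^{−i 2 k z_j} · e^{iΔφ(x, y)}.
    """
    _check_k(config, k)
    zs, maps = mirror_slices(phantom, config)
    field = np.tensordot(np.exp(-2j * k * zs), maps, axes=(0, 0))
    field *= mask.modulation
    return ComplexField(field, k, "mirror")


def _check_k(config: OpticalConfig, k: float) -> None:
    kax = config.k_axis
    klo, khi = min(kax[0], kax[-1]), max(kax[0], kax[-1])
    if not (klo - 1e-9 <= k <= khi + 1e-9):
        raise ValueError(f"wavenumber {k} outside the sweep band [{klo}, {khi}]")


# ---------------------------------------------------------------------------
# crosstalk channel
# ---------------------------------------------------------------------------

def _crosstalk_components(
    phantom: ScatteringPhantom,
    config: OpticalConfig,
    mask_seed: int,
    n_ct: int,
    mode: str,
    k_index: int | None,
    rng_key: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-depth frozen speckle maps for one mask realization.

    Returns ``(z, speckles)``: depths (n,) and complex maps (n, ny, nx).
    Each layer with µ>0 and crosstalk_strength>0 contributes ``n_ct``
    depths spanning [layer top, phantom z_extent], with total variance
    crosstalk_strength × (1 − exp(−2µd)), equally split.
    """
    if mode not in ("frozen", "per_k"):
        raise ValueError("crosstalk mode must be 'frozen' or 'per_k'")
    shape = (config.ny, config.nx)
    frac = aperture_pass_fraction(config, shape)
    z_max = phantom.z_extent
    zs: list[float] = []
    maps: list[np.ndarray] = []
    for li, layer in enumerate(phantom.layers):
        if layer.crosstalk_strength <= 0 or layer.scattering_mu <= 0 or layer.thickness <= 0:
            continue
        removed = 1.0 - np.exp(-2.0 * layer.scattering_mu * layer.thickness)
        var_total = layer.crosstalk_strength * removed
        depths = np.linspace(layer.z_top, max(z_max, layer.z_bottom), n_ct)
        sigma = np.sqrt(var_total / n_ct / 2.0)
        for q, zq in enumerate(depths):
            key = [_CT_STREAM, int(rng_key), int(phantom.seed), abs(int(mask_seed)), li, q]
            if mode == "per_k":
                key.append(int(k_index))
            rng = np.random.default_rng(np.random.SeedSequence(key))
            spk = sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
            spk = _apply_pupil(spk, pupil_transfer(config, shape)) / np.sqrt(frac)
            zs.append(zq)
            maps.append(spk)
    if not zs:
        return np.zeros(0), np.zeros((0,) + shape, dtype=complex)
    return np.asarray(zs), np.stack(maps)


def propagate_crosstalk(
    phantom: ScatteringPhantom,
    config: OpticalConfig,
    k: float,
    mask: PhaseMask,
    mode: str = "frozen",
    n_ct: int = 16,
    rng_key: int = 0,
) -> ComplexField:
    """Crosstalk speckle field at wavenumber ``k`` for one mask realization.

    Realizations for different mask seeds are statistically independent.
    ``mode='frozen'`` keeps the speckle identical across the sweep (only the
    round-trip phase e^{−2ikz} varies); ``mode='per_k'`` redraws it at every
    wavenumber.
    """
    _check_k(config, k)
    k_index = int(np.argmin(np.abs(config.k_axis - k)))
    zs, maps = _crosstalk_components(
        phantom, config, mask.seed, n_ct, mode, k_index, rng_key
    )
    shape = (config.ny, config.nx)
    if zs.size == 0:
        return ComplexField(np.zeros(shape, dtype=complex), k, "crosstalk")
    field = np.tensordot(np.exp(-2j * k * zs), maps, axes=(0, 0))
    field *= mask.modulation
    return ComplexField(field, k, "crosstalk")


def reference_field(config: OpticalConfig, k: float, mask: PhaseMask) -> ComplexField:
    """Reference-arm field A_ref·e^{iΔφ}: the mask precedes the splitter,
    so the reference carries the same phase pattern as the illumination."""
    vals = config.ref_amplitude * mask.modulation
    return ComplexField(vals.astype(complex), k, "reference")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def record_interferogram(
    sample: ComplexField,
    reference: ComplexField,
    config: OpticalConfig,
    shot_noise: bool = False,
    rng: np.random.Generator | None = None,
    photons_per_unit: float = 1000.0,
    quantize: bool = False,
) -> np.ndarray:
    """Detected intensity I = |E_s + E_r|² on the camera.

    Because the mask phase enters both fields identically, the
    mirror-interference term is mask-independent.  Optional Poisson shot
    noise (``photons_per_unit`` photoelectrons per intensity unit) and
    quantisation to ``config.bit_depth`` bits of the frame maximum.
    """
    if sample.values.shape != reference.values.shape:
        raise ValueError("sample and reference grids do not match")
    intensity = np.abs(sample.values + reference.values) ** 2
    if shot_noise:
        if rng is None:
            rng = np.random.default_rng()
        intensity = rng.poisson(intensity * photons_per_unit) / photons_per_unit
    if quantize:
        levels = 2**config.bit_depth - 1
        peak = intensity.max()
        if peak > 0:
            intensity = np.round(intensity / peak * levels) / levels * peak
    return intensity


# ---------------------------------------------------------------------------
# full acquisition
# ---------------------------------------------------------------------------

def simulate_stack(
    phantom: ScatteringPhantom,
    config: OpticalConfig,
    mask: PhaseMask,
    crosstalk: bool = True,
    ct_mode: str = "frozen",
    n_ct: int = 16,
    rng_key: int = 0,
    mirror: bool = True,
    shot_noise: bool = False,
    noise_rng: np.random.Generator | None = None,
) -> SpectralStack:
    """Interferogram stack for a single mask, vectorised over the sweep."""
    k_axis = config.k_axis
    shape = (config.ny, config.nx)
    n_k = config.n_k
    sample = np.zeros(shape + (n_k,), dtype=complex)
    if mirror:
        zs, maps = mirror_slices(phantom, config)
        if zs.size:
            phases = np.exp(-2j * np.outer(zs, k_axis))  # (n_slices, n_k)
            sample += np.tensordot(maps, phases, axes=(0, 0))
    if crosstalk:
        if ct_mode == "frozen":
            zc, cmaps = _crosstalk_components(
                phantom, config, mask.seed, n_ct, "frozen", None, rng_key
            )
            if zc.size:
                phases = np.exp(-2j * np.outer(zc, k_axis))
                sample += np.tensordot(cmaps, phases, axes=(0, 0))
        else:
            for l in range(n_k):
                f = propagate_crosstalk(
                    phantom, config, k_axis[l], mask, "per_k", n_ct, rng_key
                )
                sample[:, :, l] += f.values / mask.modulation
    # mask phase cancels against the reference in |E_s + E_r|²; attach and
    # interfere per wavelength
    a_ref = config.ref_amplitude
    intensity = np.abs(sample + a_ref) ** 2
    if shot_noise:
        if noise_rng is None:
            noise_rng = np.random.default_rng(np.random.SeedSequence([0x015E, abs(int(mask.seed))]))
        intensity = noise_rng.poisson(intensity * 1000.0) / 1000.0
    return SpectralStack(intensity, k_axis, mask_id=mask.seed, acquisition_mode="sequential")


def acquire_volume(
    phantom: ScatteringPhantom,
    config: OpticalConfig,
    masks: list[PhaseMask],
    mode: str = "sequential",
    **kwargs,
) -> list[SpectralStack]:
    """Acquire interferogram stacks over a mask sequence.

    ``sequential`` returns one stack per mask; ``camera_integrated`` returns
    a single stack whose every k-frame is the mean of the per-mask
    interferograms at that wavelength (intensity-domain integration on the
    chip).  The wavelength axis is sampled uniformly between the sweep
    edges.
    """
    if not masks:
        raise ValueError("need at least one phase mask")
    if mode not in ("sequential", "camera_integrated"):
        raise ValueError(f"unknown acquisition mode {mode!r}")
    stacks = [simulate_stack(phantom, config, m, **kwargs) for m in masks]
    if mode == "sequential":
        return stacks
    mean = np.mean([s.data for s in stacks], axis=0)
    return [SpectralStack(mean, config.k_axis, mask_id="integrated",
                          acquisition_mode="camera_integrated")]
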