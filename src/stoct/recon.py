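"""Fourier-domain volumetric reconstruction and fixed-pattern filtering.

A DC-removed spectral interferogram stack I(y, x; k) is turned into a
complex volume by a per-pixel Fourier transform along the wavenumber axis:
the fringe frequency of a reflector at depth z is 2z, so after resampling
to a uniform k grid, zero padding (for finer axial sampling) and an FFT,
the positive-depth half of the transform is the A-scan.  Only that half is
kept — the other half is its Hermitian mirror for real detector data.

Fixed-pattern noise common to every plane of a volume shows up as isolated
peaks in the 2-D spatial-frequency plane; a notch mask estimated from the
depth-integrated spectrum removes it.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from scipy import interpolate, ndimage, signal

from .forward import SpectralStack


@dataclasses.dataclass
class ReconVolume:
    """Complex volumetric reconstruction with depth axis and provenance.

    ``data`` has shape (ny, nx, nz); ``z_axis`` is in µm.  ``provenance``
    is an append-only list of the processing stages applied, each a dict of
    the stage name and its parameters.
    """

    data: np.ndarray
    z_axis: np.ndarray
    provenance: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (ny, nx, nz)")
        if len(self.z_axis) != self.data.shape[2]:
            raise ValueError("z_axis length must equal nz")

    def log_stage(self, name: str, **params) -> None:
        self.provenance.append({"stage": name, **params})

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def enface(self, iz: int) -> np.ndarray:
        return self.data[:, :, iz]

    def bscan(self, plane: str = "XZ", index: int | None = None) -> np.ndarray:
        """Extract a B-scan: 'XZ' at row index (default middle) or 'YZ' at
        column index."""
        if plane == "XZ":
            i = self.data.shape[0] // 2 if index is None else index
            return self.data[i, :, :]
        if plane == "YZ":
            i = self.data.shape[1] // 2 if index is None else index
            return self.data[:, i, :]
        raise ValueError("plane must be 'XZ' or 'YZ'")

    def copy(self) -> "ReconVolume":
        return ReconVolume(self.data.copy(), self.z_axis.copy(),
                           copy.deepcopy(self.provenance))


# ---------------------------------------------------------------------------
# uniform-k resampling and depth FFT
# ---------------------------------------------------------------------------

def uniform_k_spectrum(stack: SpectralStack) -> tuple[np.ndarray, np.ndarray, bool]:
    """Ascending, uniformly sampled spectral data.

    Returns ``(data, k_axis, resampled)``.  Swept sources tune nearly
    linearly in wavelength, so k = 2π/λ is non-uniform; when the spacing
    deviates by more than 0.1% the data are cubic-interpolated onto a
    uniform k grid of the same length.
    """
    k = np.asarray(stack.k_axis, dtype=float)
    data = stack.data
    if k[0] > k[-1]:
        k = k[::-1]
        data = data[:, :, ::-1]
    dk = np.diff(k)
    if np.any(dk <= 0):
        raise ValueError("k_axis must be strictly monotonic")
    nonuni = (dk.max() - dk.min()) / dk.mean()
    if nonuni <= 1e-3:
        return data, k, False
    k_u = np.linspace(k[0], k[-1], k.size)
    spline = interpolate.CubicSpline(k, data, axis=2)
    return spline(k_u), k_u, True


def analytic_spectrum(stack: SpectralStack) -> tuple[np.ndarray, np.ndarray]:
    """Complex (analytic) spectral fringe on a uniform ascending k axis.

    The analytic signal along k carries the one-sided fringe content, which
    phase correctors (dispersion, motion) multiply before the depth FFT.
    """
    data, k_u, _ = uniform_k_spectrum(stack)
    return signal.hilbert(data, axis=2), k_u


def reconstruct_depth(
    stack: SpectralStack,
    pad_factor: int = 1,
    phase_corrector=None,
) -> ReconVolume:
    """Depth reconstruction: per-pixel FFT along k with zero padding.

    ``pad_factor`` (integer >= 1) zero-pads the spectrum to n_k×pad_factor
    samples before the FFT to refine axial sampling; the positive-depth
    half (nz = n_k×pad_factor/2 bins) is retained.  The depth step is
    Δz = π/(N_pad·δk) with δk the uniform wavenumber spacing, i.e. the
    total depth range is π/δk.

    ``phase_corrector`` (an object with a ``modulation(k_axis)`` method,
    e.g. :class:`stoct.dispersion.PhaseCorrector`) multiplies the analytic
    spectrum before the transform.
    """
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError("pad_factor must be an integer >= 1")
    if phase_corrector is None:
        data, k_u, resampled = uniform_k_spectrum(stack)
        spec = data.astype(complex)
    else:
        spec, k_u = analytic_spectrum(stack)
        resampled = True
        spec = spec * phase_corrector.modulation(k_u)
    n_k = spec.shape[2]
    n_pad = n_k * int(pad_factor)
    a = np.fft.fft(spec, n=n_pad, axis=2)
    nz = n_pad // 2
    dk = k_u[1] - k_u[0]
    z_axis = np.arange(nz) * np.pi / (n_pad * dk)
    # The depth encoding is e^{−i2kz}; the retained positive-frequency FFT
    # half holds the conjugate of that component, so the volume is
    # conjugated to restore the sample field's own lateral phase (pupil
    # aberrations then appear with the forward sign and can be corrected
    # by applying the negated pupil phase).
    vol = ReconVolume(np.conj(a[:, :, :nz]), z_axis)
    vol.log_stage(
        "reconstruct_depth",
        pad_factor=int(pad_factor),
        resampled_uniform_k=bool(resampled),
        dc_removed_input=bool(stack.dc_removed),
        phase_corrector=None if phase_corrector is None else phase_corrector.describe(),
    )
    return vol


def fit_attenuation_profile(
    volume: ReconVolume, z_range: tuple[float, float]
) -> dict:
    """Beer–Lambert fit of the depth profile of reconstruction amplitude.

    The laterally averaged amplitude A(z) of a homogeneous scattering layer
    decays as exp(−2µz) (round-trip attenuation of the field); a linear fit
    of ln A against z over ``z_range`` returns µ = −slope/2, together with
    the RMS residual of the log-profile fit.
    """
    z = np.asarray(volume.z_axis, dtype=float)
    sel = (z >= z_range[0]) & (z <= z_range[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 depth bins in z_range")
    prof = np.mean(np.abs(volume.data), axis=(0, 1))[sel]
    zz = z[sel]
    if np.any(prof <= 0):
        raise ValueError("non-positive amplitude in the fit range")
    logp = np.log(prof)
    slope, intercept = np.polyfit(zz, logp, 1)
    resid = logp - (slope * zz + intercept)
    return {
        "mu": float(-slope / 2.0),
        "intercept": float(intercept),
        "rms_log_residual": float(np.sqrt(np.mean(resid**2))),
        "n_depths": int(sel.sum()),
        "z_range": [float(z_range[0]), float(z_range[1])],
    }


# ---------------------------------------------------------------------------
# fixed-pattern spatial filtering
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FixedPatternFilter:
    """Notch mask in the (unshifted) 2-D spatial-frequency plane.

    True entries are zeroed.  The mask is point-symmetric through the
    frequency origin so that filtering a real image keeps it real.
    """

    notch_mask: np.ndarray
    detection_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.notch_mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("notch mask must be 2-D")
        if not np.array_equal(m, _point_reflect(m)):
            raise ValueError("notch mask must be point-symmetric through the origin")

    @property
    def n_notched(self) -> int:
        return int(self.notch_mask.sum())


def _point_reflect(mask: np.ndarray) -> np.ndarray:
    """f → −f on the unshifted FFT grid: index i → (−i) mod N."""
    return np.roll(np.flip(mask, axis=(0, 1)), shift=(1, 1), axis=(0, 1))


def _planes_of(obj) -> np.ndarray:
    """(n_planes, ny, nx) view of a SpectralStack or ReconVolume."""
    if isinstance(obj, SpectralStack):
        return np.moveaxis(obj.data, 2, 0)
    if isinstance(obj, ReconVolume):
        return np.moveaxis(obj.data, 2, 0)
    arr = np.asarray(obj)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D array, SpectralStack or ReconVolume")
    return np.moveaxis(arr, 2, 0)


def estimate_fixed_pattern_filter(
    volume,
    threshold: float = 4.0,
    background_window: int = 9,
    dc_guard_radius: float = 3.0,
) -> FixedPatternFilter:
    """Detect fixed-pattern spatial frequencies common to all planes.

    Each plane is 2-D Fourier transformed; magnitudes are summed along the
    depth/spectral axis; a median-filtered background is estimated; bins
    exceeding ``threshold`` × background outside a DC guard disk are
    flagged and point-symmetrised into a notch mask.
    """
    planes = _planes_of(volume)
    if planes.shape[0] < 4:
        raise ValueError("need at least 4 planes to estimate the filter")
    accum = np.zeros(planes.shape[1:], dtype=float)
    for p in planes:
        accum += np.abs(np.fft.fft2(p))
    accum_sh = np.fft.fftshift(accum)
    background = ndimage.median_filter(accum_sh, size=background_window, mode="wrap")
    ny, nx = accum.shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    guard = (yy - cy) ** 2 + (xx - cx) ** 2 <= dc_guard_radius**2
    flags = (accum_sh > threshold * np.maximum(background, 1e-300)) & ~guard
    mask = np.fft.ifftshift(flags)
    mask = mask | _point_reflect(mask)
    return FixedPatternFilter(
        notch_mask=mask,
        detection_params={
            "threshold": threshold,
            "background_window": background_window,
            "dc_guard_radius": dc_guard_radius,
        },
    )


def apply_spatial_filter(obj, filt: FixedPatternFilter):
    """Zero the notched spatial frequencies in every plane.

    Accepts a SpectralStack, a ReconVolume or a bare 3-D array and returns
    the same type; real inputs stay real (residual imaginary part below
    1e−9 relative is discarded).
    """
    planes = _planes_of(obj)
    if filt.notch_mask.shape != planes.shape[1:]:
        raise ValueError("filter grid does not match the data planes")
    keep = ~filt.notch_mask
    out = np.empty_like(planes, dtype=complex)
    for i, p in enumerate(planes):
        out[i] = np.fft.ifft2(np.fft.fft2(p) * keep)
    was_real = np.isrealobj(planes)
    if was_real:
        scale = np.max(np.abs(out)) or 1.0
        resid = np.max(np.abs(out.imag)) / scale
        if resid > 1e-9:
            raise AssertionError(f"real input grew imaginary part ({resid:.2e} relative)")
        out = out.real
    data = np.moveaxis(out, 0, 2)
    if isinstance(obj, SpectralStack):
        return SpectralStack(data, obj.k_axis, obj.mask_id, obj.acquisition_mode,
                             dc_removed=True)
    if isinstance(obj, ReconVolume):
        vol = ReconVolume(data, obj.z_axis.copy(), copy.deepcopy(obj.provenance))
        vol.log_stage("apply_spatial_filter", n_notched=filt.n_notched,
                      **filt.detection_params)
        return vol
    return data
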