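"""Computational aberration correction of complex en-face images.

Two estimators operate in the 2-D spatial-frequency (pupil) plane of a
complex en-face reconstruction:

* **split-aperture defocus** — the pupil is cut into two half-apertures;
  a defocus phase α·ρ² tilts each half differently, so the two sub-images
  are mutually displaced by an amount proportional to α.  Measuring the
  displacement by cross-correlation across several depths and fitting it
  linearly against depth yields the defocus coefficient and its rate of
  change with depth;

* **entropy-driven Zernike search** — a variable pupil phase built from
  weighted Zernike polynomials is tuned, one coefficient at a time, to
  sharpen the image.  Sharpness is measured by the Shannon entropy
  S = −Σ p ln p of the normalised intensity p = I/ΣI: a sharp image
  concentrates energy in few pixels and has *low* entropy, so the default
  search direction minimises S (switchable).

Zernike polynomials use Noll indexing with RMS normalisation, defined on
the unit disk inscribed in the frequency plane; outside the disk the phase
is zero, so every correction is unit-modulus and conserves spectral energy.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize
from skimage.registration import phase_cross_correlation


# ---------------------------------------------------------------------------
# Zernike polynomials (Noll indexing, RMS-normalised)
# ---------------------------------------------------------------------------

def noll_to_nm(j: int) -> tuple[int, int]:
    """Map Noll index j >= 1 to (radial order n, azimuthal frequency m)."""
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 >= n + 1:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s) * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-indexed Zernike polynomial on ρ <= 1 (RMS normalised to 1)."""
    n, m = noll_to_nm(j)
    r = _radial(n, m, rho)
    if m == 0:
        return math.sqrt(n + 1) * r
    if m > 0:
        return math.sqrt(2 * (n + 1)) * r * np.cos(m * theta)
    return math.sqrt(2 * (n + 1)) * r * np.sin(-m * theta)


@dataclasses.dataclass(frozen=True)
class ZernikeCoeffs:
    """Pupil-phase expansion: {Noll index: coefficient in radians}.

    Piston (j=1) is excluded from optimisation by default; tip/tilt
    (j=2,3) merely translate the image and are excluded as well.
    """

    coefficients: dict
    max_order: int = 4

    def __post_init__(self) -> None:
        for j, c in self.coefficients.items():
            if j < 1:
                raise ValueError("Noll indices start at 1")
            if not np.isfinite(c):
                raise ValueError("coefficients must be finite")

    def get(self, j: int) -> float:
        return float(self.coefficients.get(j, 0.0))

    def __neg__(self) -> "ZernikeCoeffs":
        return ZernikeCoeffs({j: -c for j, c in self.coefficients.items()}, self.max_order)


def noll_indices_up_to(max_order: int, skip: tuple[int, ...] = (1, 2, 3)) -> list[int]:
    """All Noll indices with radial order <= max_order, minus ``skip``."""
    jmax = (max_order + 1) * (max_order + 2) // 2
    return [j for j in range(1, jmax + 1) if j not in skip]


def _pupil_coords(shape: tuple[int, int], pupil_fraction: float = 1.0):
    """(ρ, θ, inside) on the unshifted FFT grid; the pupil is the disk of
    radius ``pupil_fraction`` × the inscribed Nyquist circle."""
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    u = fx[None, :]
    v = fy[:, None]
    f_r = 0.5 * pupil_fraction
    rho = np.sqrt(u**2 + v**2) / f_r
    theta = np.arctan2(v, u) * np.ones_like(rho)
    inside = rho <= 1.0
    return rho, theta, inside


def zernike_phase_map(
    shape: tuple[int, int], coeffs: ZernikeCoeffs, pupil_fraction: float = 1.0
) -> np.ndarray:
    """Pupil phase Σ c_j Z_j on the unshifted FFT grid (0 outside the disk)."""
    rho, theta, inside = _pupil_coords(shape, pupil_fraction)
    phase = np.zeros(shape)
    for j, c in coeffs.coefficients.items():
        if c != 0.0:
            phase[inside] += c * zernike(j, rho[inside], theta[inside])
    return phase


def apply_pupil_phase(image: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Multiply the image spectrum by the unit-modulus factor e^{iφ(f)}."""
    return np.fft.ifft2(np.fft.fft2(image) * np.exp(1j * phase))


def defocus_phase_map(
    shape: tuple[int, int], alpha: float, pupil_fraction: float = 1.0
) -> np.ndarray:
    """Pure defocus pupil phase α·ρ² (zero outside the pupil disk)."""
    rho, _, inside = _pupil_coords(shape, pupil_fraction)
    return np.where(inside, alpha * rho**2, 0.0)


# ---------------------------------------------------------------------------
# split-aperture defocus estimation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DefocusEstimate:
    """Linear fit of sub-aperture displacement against depth.

    ``alpha`` is the defocus pupil-phase coefficient α (rad at the pupil
    edge, φ = α·ρ²) evaluated at the centre of the fitted depth range;
    ``slope_per_um`` its rate of change with depth; ``coeffs`` the same
    defocus expressed as a Noll Z4 Zernike coefficient (α = 2√3·c₄)."""

    alpha: float
    alpha_stderr: float
    slope_per_um: float
    coeffs: ZernikeCoeffs
    n_depths: int
    depths: np.ndarray
    displacements: np.ndarray


def _split_aperture_displacement(
    enface: np.ndarray, pupil_fraction: float, upsample: int
) -> tuple[float, float]:
    """Lateral displacement between the two half-aperture sub-images and the
    energy-weighted centroid separation of the two half-apertures (bins)."""
    ny, nx = enface.shape
    spec = np.fft.fftshift(np.fft.fft2(enface))
    u = np.arange(nx) - nx // 2  # frequency bins (shifted layout)
    left = np.broadcast_to(u[None, :] < 0, spec.shape)
    right = np.broadcast_to(u[None, :] > 0, spec.shape)
    sub_l = np.fft.ifft2(np.fft.ifftshift(spec * left))
    sub_r = np.fft.ifft2(np.fft.ifftshift(spec * right))
    shift, _, _ = phase_cross_correlation(
        np.abs(sub_l), np.abs(sub_r), upsample_factor=upsample, normalization=None
    )
    dx = float(shift[1])  # displacement of the right sub-image w.r.t. the left
    e = np.abs(spec) ** 2
    uw = np.broadcast_to(u[None, :], e.shape)
    el, er = e[left].sum(), e[right].sum()
    if el == 0 or er == 0:
        raise ValueError("a half-aperture carries no energy")
    cen_l = (e[left] * uw[left]).sum() / el
    cen_r = (e[right] * uw[right]).sum() / er
    return dx, float(cen_r - cen_l)


def subaperture_defocus(
    volume,
    depth_range: tuple[float, float] | None = None,
    pupil_fraction: float = 1.0,
    upsample: int = 100,
    min_energy_frac: float = 1e-3,
    n_iter: int = 3,
) -> DefocusEstimate:
    """Estimate defocus from sub-aperture image shear across depth.

    For each en-face plane in ``depth_range`` with sufficient energy, the
    spectrum is split into left/right half-apertures along f_x, each is
    inverse-transformed, and their mutual displacement is measured by
    cross-correlation with sub-pixel interpolation.  A pupil phase α·ρ²
    displaces the sub-images by Δx = α·(u̅_R−u̅_L)·N/(2π·R²) pixels (u̅ the
    energy-weighted half-aperture centroids), so each displacement converts
    to an α; the per-depth values are fitted linearly against depth.

    Because the residual quadratic phase also blurs the sub-images (which
    attenuates the correlation-measured shift), the estimate is refined
    iteratively: the fitted α(z) is applied as a correction and the
    residual displacement re-measured; at zero residual the estimator is
    unbiased.
    """
    planes = volume.data
    z_axis = np.asarray(volume.z_axis, dtype=float)
    ny, nx = planes.shape[:2]
    energies = np.sum(np.abs(planes) ** 2, axis=(0, 1))
    sel = energies >= min_energy_frac * energies.max()
    if depth_range is not None:
        sel &= (z_axis >= depth_range[0]) & (z_axis <= depth_range[1])
    idx = np.nonzero(sel)[0]
    if idx.size < 3:
        raise ValueError("need >= 3 depths with signal energy in the range")
    r_bins = 0.5 * pupil_fraction * nx  # pupil radius in frequency bins
    depths = z_axis[idx]
    z_mid = 0.5 * (depths.min() + depths.max())
    acc = np.zeros(2)  # accumulated [slope, alpha at z_mid]
    alphas = np.zeros(idx.size)
    disps = np.zeros(idx.size)
    for _ in range(max(1, n_iter)):
        for i, iz in enumerate(idx):
            alpha_corr = acc[1] + acc[0] * (z_axis[iz] - z_mid)
            plane = planes[:, :, iz]
            if alpha_corr != 0.0:
                plane = apply_pupil_phase(
                    plane, defocus_phase_map((ny, nx), -alpha_corr, pupil_fraction)
                )
            dx, dcen = _split_aperture_displacement(plane, pupil_fraction, upsample)
            # shift (pixels) from the pupil-phase slope x = (N/2π)·∂φ/∂u,
            # with ∂(αρ²)/∂u = 2αu/R² taken at the aperture centroid
            alphas[i] = alpha_corr + dx * np.pi * r_bins**2 / (nx * dcen)
            disps[i] = dx
        coeff = np.polyfit(depths - z_mid, alphas, 1)
        if abs(coeff[1] - acc[1]) < 1e-4 and abs(coeff[0] - acc[0]) < 1e-6:
            acc = coeff
            break
        acc = coeff
    alpha_mid = float(acc[1])
    resid = alphas - np.polyval(acc, depths - z_mid)
    dof = max(idx.size - 2, 1)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / idx.size))
    return DefocusEstimate(
        alpha=alpha_mid,
        alpha_stderr=stderr,
        slope_per_um=float(acc[0]),
        coeffs=ZernikeCoeffs({4: alpha_mid / (2.0 * math.sqrt(3.0))}, max_order=2),
        n_depths=int(idx.size),
        depths=depths,
        displacements=disps,
    )


# ---------------------------------------------------------------------------
# entropy-driven Zernike correction
# ---------------------------------------------------------------------------

def image_entropy(image: np.ndarray) -> float:
    """Shannon entropy −Σ p ln p of normalised intensity p = I/ΣI."""
    inten = np.abs(image) ** 2
    total = inten.sum()
    if total == 0:
        raise ValueError("zero-energy image")
    p = inten.ravel() / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def zernike_aberration_correct(
    enface: np.ndarray,
    max_order: int = 4,
    init: ZernikeCoeffs | None = None,
    pupil_fraction: float = 1.0,
    direction: str = "min",
    search_range: float = 4.0,
    coarse_points: int = 17,
    tol: float = 1e-4,
    max_cycles: int = 10,
) -> tuple[np.ndarray, ZernikeCoeffs]:
    """Iterative per-coefficient Zernike sharpening of a complex image.

    Coordinate descent over all Noll coefficients of radial order 2..
    ``max_order`` (piston/tip/tilt excluded): each coefficient is bracketed
    by a coarse scan over ±``search_range`` rad and refined by bounded
    scalar minimisation of the entropy metric; cycles repeat until the
    per-cycle improvement falls below ``tol``.

    Returns the corrected image and the *estimated aberration* — the
    negation of the applied corrector phase, so that recovering an
    injected aberration yields coefficients of the same sign.
    """
    if max_order < 2:
        raise ValueError("max_order must be >= 2")
    enface = np.asarray(enface)
    if enface.ndim != 2:
        raise ValueError("enface must be a 2-D complex image")
    if np.ptp(np.abs(enface)) == 0:
        raise ValueError("image is constant")
    image_entropy(enface)  # raises on zero energy
    sign = -1.0 if direction == "min" else 1.0

    rho, theta, inside = _pupil_coords(enface.shape, pupil_fraction)
    js = noll_indices_up_to(max_order)
    basis = {j: np.where(inside, zernike(j, np.where(inside, rho, 0.0), theta), 0.0)
             for j in js}
    spec0 = np.fft.fft2(enface)
    coeffs = {j: (init.get(j) if init is not None else 0.0) for j in js}

    def metric(cvec: dict) -> float:
        phase = np.zeros(enface.shape)
        for j, c in cvec.items():
            if c != 0.0:
                phase += c * basis[j]
        img = np.fft.ifft2(spec0 * np.exp(1j * phase))
        return sign * (-image_entropy(img))  # minimised; sign flips direction

    current = metric(coeffs)
    for _cycle in range(max_cycles):
        start = current
        for j in js:
            base = coeffs[j]
            # multi-scale bracket: coarse scan, then bounded refinement
            grid = base + np.linspace(-search_range, search_range, coarse_points)
            vals = []
            for g in grid:
                trial = dict(coeffs)
                trial[j] = g
                vals.append(metric(trial))
            gi = int(np.argmin(vals))
            lo = grid[max(gi - 1, 0)]
            hi = grid[min(gi + 1, len(grid) - 1)]

            def f1(c: float) -> float:
                trial = dict(coeffs)
                trial[j] = c
                return metric(trial)

            res = optimize.minimize_scalar(
                f1, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-3, "maxiter": 50},
            )
            cand = float(res.x) if res.fun < min(vals[gi], current) else grid[gi]
            cand_val = min(res.fun, vals[gi])
            if cand_val < current:
                coeffs[j] = cand if res.fun <= vals[gi] else float(grid[gi])
                current = cand_val
        if start - current < tol:
            break

    applied = ZernikeCoeffs(dict(coeffs), max_order=max_order)
    phase = zernike_phase_map(enface.shape, applied, pupil_fraction)
    corrected = np.fft.ifft2(spec0 * np.exp(1j * phase))
    return corrected, -applied
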