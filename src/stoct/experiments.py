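"""Canned simulation studies: the package's benchmark experiments.

Each function sets up a phantom and acquisition, runs the full pipeline
(simulate → average → reconstruct → correct) and measures one quantitative
behavior of the method: the √M crosstalk-averaging law, coherence-matrix
diagonalisation, Rician noise statistics versus mask count, Beer–Lambert
attenuation recovery, the incoherent √2 resolution gain, and
inject-and-recover checks of the three computational corrections.

Problem sizes are chosen so every study runs in seconds on one CPU; the
measured exponents, ratios and recovery errors are size-independent
properties of the method.
"""

from __future__ import annotations

import numpy as np

from .aberration import (
    ZernikeCoeffs,
    apply_pupil_phase,
    defocus_phase_map,
    subaperture_defocus,
    zernike_aberration_correct,
    zernike_phase_map,
)
from .coherence import build_G, diagonality, fit_rician
from .config import OpticalConfig
from .dispersion import PhaseCorrector, apply_dispersion, kurtosis_phase_correct
from .forward import propagate_crosstalk, propagate_mirror, simulate_stack
from .masks import generate_mask_ensemble, generate_phase_mask
from .phantom import make_phantom
from .recon import ReconVolume, fit_attenuation_profile, reconstruct_depth
from .stoc import average_stacks, crosstalk_residual, fringe_band_rms, remove_dc, suppression_metrics


def _diffuser_config(nx=32, n_k=64):
    return OpticalConfig(nx=nx, ny=nx, n_k=n_k, na_det=0.3, na_ill=0.1,
                         pixel_pitch_obj=2.0, ref_amplitude=10.0)


# ---------------------------------------------------------------------------
# crosstalk averaging
# ---------------------------------------------------------------------------

def crosstalk_decay_slope(
    seed: int = 0,
    mask_counts: tuple[int, ...] = (4, 16, 64, 256),
    n_replicates: int = 20,
    grid: int = 32,
    n_k: int = 64,
) -> dict:
    """Fit the power law of residual crosstalk RMS versus mask count M.

    Crosstalk-only interferogram stacks (ballistic channel off) are
    averaged over growing mask ensembles; the fringe-band RMS follows
    M^(−1/2).  Returns the per-replicate log-log slopes and their mean.
    """
    cfg = _diffuser_config(grid, n_k)
    ph = make_phantom("plane_behind_diffuser", cfg, mu=5e-3, thickness=100.0,
                      z_plane=150.0, crosstalk_strength=1.0)
    slopes = []
    for rep in range(n_replicates):
        masks = generate_mask_ensemble(cfg, "slm", max(mask_counts),
                                       seed=seed * 1000 + rep)
        stacks = [simulate_stack(ph, cfg, m, mirror=False, n_ct=8,
                                 rng_key=seed * 1000 + rep) for m in masks]
        rms = [fringe_band_rms(average_stacks(stacks[:m])) for m in mask_counts]
        slopes.append(float(np.polyfit(np.log(mask_counts), np.log(rms), 1)[0]))
    return {"slopes": slopes, "mean_slope": float(np.mean(slopes)),
            "mask_counts": list(mask_counts)}


def suppression_factor_at_mode_count(seed: int = 0, n_masks: int = 846,
                                     grid: int = 16, n_k: int = 64) -> float:
    """Crosstalk suppression factor after averaging over ``n_masks`` masks
    (defaults to the mode count of the reference multimode fiber, whose
    expected attenuation is √846 ≈ 29)."""
    cfg = _diffuser_config(grid, n_k)
    ph = make_phantom("plane_behind_diffuser", cfg, mu=5e-3, thickness=100.0,
                      z_plane=150.0, crosstalk_strength=1.0)
    masks = generate_mask_ensemble(cfg, "slm", n_masks, seed=seed)
    mirror_only = simulate_stack(ph, cfg, masks[0], crosstalk=False)
    stacks = [simulate_stack(ph, cfg, m, n_ct=8, rng_key=seed) for m in masks]
    rep = suppression_metrics(average_stacks(stacks), mirror_only,
                              crosstalk_residual(stacks[0], mirror_only),
                              n_masks=n_masks)
    return rep.suppression_factor


# ---------------------------------------------------------------------------
# coherence matrix
# ---------------------------------------------------------------------------

def gmatrix_diagonality_ratio(seed: int = 0, n_masks: int = 256,
                              roi_size: int = 16, grid: int = 32) -> dict:
    """Diagonality of the coherence matrix under STOC modulation versus
    coherent (flat-mask) illumination, on a moderately scattering sample
    where the ballistic field keeps a substantial energy share."""
    cfg = _diffuser_config(grid, 64)
    ph = make_phantom("plane_behind_diffuser", cfg, mu=2e-3, thickness=100.0,
                      z_plane=150.0, crosstalk_strength=0.5, reflectivity=0.9)
    k_mid = float(cfg.k_axis[cfg.n_k // 2])
    lo = (grid - roi_size) // 2
    roi = (slice(lo, lo + roi_size), slice(lo, lo + roi_size))

    def ensemble(kind, seed0):
        frames = []
        for m in generate_mask_ensemble(cfg, kind, n_masks, seed=seed0):
            f = propagate_mirror(ph, cfg, k_mid, m).values
            f = f + propagate_crosstalk(ph, cfg, k_mid, m, n_ct=8).values
            frames.append(f)
        return np.stack(frames)

    d_stoc = diagonality(build_G(ensemble("slm", seed), roi=roi))
    d_coh = diagonality(build_G(ensemble("flat", seed + 7919), roi=roi))
    return {"stoc": float(d_stoc), "coherent": float(d_coh),
            "ratio": float(d_stoc / d_coh)}


# ---------------------------------------------------------------------------
# Rician statistics
# ---------------------------------------------------------------------------

def rician_noise_vs_masks(seed: int = 0,
                          mask_counts: tuple[int, ...] = (1, 4, 16, 64),
                          grid: int = 48, n_k: int = 128) -> dict:
    """σ_n² and I_d of the normalised en-face intensity at the target plane
    as the number of averaged masks grows."""
    cfg = _diffuser_config(grid, n_k)
    ph = make_phantom("plane_behind_diffuser", cfg, mu=5e-3, thickness=100.0,
                      z_plane=150.0, crosstalk_strength=1.0)
    masks = generate_mask_ensemble(cfg, "slm", max(mask_counts), seed=seed)
    stacks = [simulate_stack(ph, cfg, m, n_ct=8, rng_key=seed) for m in masks]
    sigma, i_det = [], []
    for m in mask_counts:
        vol = reconstruct_depth(remove_dc(average_stacks(stacks[:m]),
                                          "mean_subtract"), pad_factor=2)
        iz = int(np.argmin(np.abs(vol.z_axis - 150.0)))
        inten = np.abs(vol.enface(iz)) ** 2
        fit = fit_rician(inten / inten.mean())
        sigma.append(fit.sigma_n2)
        i_det.append(fit.i_det)
    return {"mask_counts": list(mask_counts), "sigma_n2": sigma, "i_det": i_det}


# ---------------------------------------------------------------------------
# two-layer phantom attenuation
# ---------------------------------------------------------------------------

def two_layer_attenuation_recovery(seed: int = 0, n_masks: int = 64,
                                   grid: int = 32, n_k: int = 256) -> dict:
    """Beer–Lambert µ recovery from STOC (mask-averaged) versus coherent
    (single flat-mask) reconstructions of the two-layer scattering phantom."""
    cfg = _diffuser_config(grid, n_k)
    mu1 = 3e-3
    ph = make_phantom("two_layer_slab_with_defect", cfg, mu1=mu1, mu2=6e-3,
                      t1=200.0, t2=200.0, z_top=50.0, defect_radius=0.0,
                      r1=0.01, r2=0.01, seed=seed)
    masks = generate_mask_ensemble(cfg, "slm", n_masks, seed=seed)
    stacks = [simulate_stack(ph, cfg, m, n_ct=16, rng_key=seed) for m in masks]
    v_stoc = reconstruct_depth(remove_dc(average_stacks(stacks), "mean_subtract"),
                               pad_factor=2)
    v_coh = reconstruct_depth(remove_dc(stacks[0], "mean_subtract"), pad_factor=2)
    fit_range = (70.0, 230.0)
    mu_stoc = fit_attenuation_profile(v_stoc, fit_range)["mu"]
    mu_coh = fit_attenuation_profile(v_coh, fit_range)["mu"]
    return {
        "mu_true": mu1,
        "mu_stoc": mu_stoc,
        "mu_coherent": mu_coh,
        "stoc_error": abs(mu_stoc - mu1) / mu1,
        "coherent_error": abs(mu_coh - mu1) / mu1,
    }


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------

def _fwhm_1d(profile: np.ndarray, upsample: int = 16) -> float:
    """FWHM in pixels via exact band-limited (zero-padded FFT) interpolation."""
    n = len(profile)
    spec = np.fft.fft(profile)
    padded = np.zeros(n * upsample, complex)
    padded[: n // 2] = spec[: n // 2]
    padded[-(n // 2):] = spec[-(n // 2):]
    fine = np.real(np.fft.ifft(padded)) * upsample
    fine -= fine.min()
    pk = int(np.argmax(fine))
    half = fine[pk] / 2
    lo = pk
    while lo > 0 and fine[lo] > half:
        lo -= 1
    hi = pk
    while hi < len(fine) - 1 and fine[hi] > half:
        hi += 1
    return (hi - lo) / upsample


def psf_fwhm_ratio(seed: int = 0, grid: int = 64) -> dict:
    """Lateral FWHM of the mask-averaged *intensity* PSF over the coherent
    single-mask *amplitude* PSF for a point target (expected 1/√2 for a
    Gaussian pupil; ≈0.73 for a hard circular aperture)."""
    cfg = OpticalConfig(nx=grid, ny=grid, n_k=64, na_det=0.12, na_ill=0.05,
                        pixel_pitch_obj=2.0, ref_amplitude=10.0)
    ph = make_phantom("point_target", cfg, z0=100.0)

    def enface(mask):
        st = remove_dc(simulate_stack(ph, cfg, mask, crosstalk=False),
                       "mean_subtract")
        vol = reconstruct_depth(st, pad_factor=2)
        iz = int(np.argmin(np.abs(vol.z_axis - 100.0)))
        return vol.enface(iz)

    coh_amp = np.abs(enface(generate_phase_mask(cfg, "flat", seed)))
    masks = generate_mask_ensemble(cfg, "slm", 8, seed=seed)
    avg_int = np.mean([np.abs(enface(m)) ** 2 for m in masks], axis=0)
    row = grid // 2
    fwhm_amp = _fwhm_1d(coh_amp[row, :])
    fwhm_int = _fwhm_1d(avg_int[row, :])
    return {"fwhm_coherent_amplitude": fwhm_amp,
            "fwhm_incoherent_intensity": fwhm_int,
            "ratio": fwhm_int / fwhm_amp}


# ---------------------------------------------------------------------------
# computational corrections: inject and recover
# ---------------------------------------------------------------------------

def dispersion_recovery(seed: int = 0, a2: float = 6.0, a3: float = -3.0,
                        grid: int = 32, n_k: int = 256) -> dict:
    """Inject a known polynomial dispersion and recover it with the
    kurtosis stage on a specular calibration plane."""
    cfg = _diffuser_config(grid, n_k)
    ph = make_phantom("plane_behind_diffuser", cfg, mu=0.0, z_plane=250.0,
                      reflectivity=0.2)
    flat = generate_phase_mask(cfg, "flat", seed)
    st = remove_dc(simulate_stack(ph, cfg, flat, crosstalk=False), "mean_subtract")
    injected = PhaseCorrector(np.array([0.0, a2, a3, 0.0, 0.0]))
    _, corrector = kurtosis_phase_correct(apply_dispersion(st, injected))
    rec2, rec3 = -corrector.a[1], -corrector.a[2]
    return {"injected": [a2, a3], "recovered": [float(rec2), float(rec3)],
            "errors": [abs(rec2 - a2) / abs(a2), abs(rec3 - a3) / abs(a3)]}


def _point_grid(shape, seed, n_points=40, band=0.35):
    ny, nx = shape
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, complex)
    img[rng.integers(4, ny - 4, n_points), rng.integers(4, nx - 4, n_points)] = (
        1.0 + 0.5 * rng.random(n_points)
    )
    fy = np.fft.fftfreq(ny)
    fx = np.fft.fftfreq(nx)
    lp = (fy[:, None] ** 2 + fx[None, :] ** 2) <= band**2
    return np.fft.ifft2(np.fft.fft2(img) * lp)


def defocus_recovery(seed: int = 0, alpha: float = 3.0, grid: int = 64,
                     n_depths: int = 8) -> dict:
    """Inject a known defocus pupil phase α·ρ² on a stack of point-grid
    planes and recover α with the split-aperture estimator."""
    planes = [
        apply_pupil_phase(_point_grid((grid, grid), seed * 100 + i),
                          defocus_phase_map((grid, grid), alpha))
        for i in range(n_depths)
    ]
    vol = ReconVolume(np.stack(planes, axis=2), np.arange(n_depths) * 10.0)
    est = subaperture_defocus(vol)
    return {"injected": alpha, "recovered": est.alpha,
            "error": abs(est.alpha - alpha) / abs(alpha),
            "stderr": est.alpha_stderr}


def astigmatism_recovery(seed: int = 0, coeff: float = 2.0, noll_index: int = 6,
                         grid: int = 64) -> dict:
    """Inject a known astigmatism on a sparse point-grid image and recover
    it with the entropy-driven Zernike search."""
    img = _point_grid((grid, grid), seed + 55)
    injected = ZernikeCoeffs({noll_index: coeff}, max_order=2)
    blurred = apply_pupil_phase(img, zernike_phase_map((grid, grid), injected))
    _, recovered = zernike_aberration_correct(blurred, max_order=2)
    rec = recovered.get(noll_index)
    return {"injected": coeff, "recovered": rec,
            "error": abs(rec - coeff) / abs(coeff)}
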