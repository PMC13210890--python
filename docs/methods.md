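# Methods

## Forward model

The detected sample field at each wavenumber k = 2π/λ is the sum of two
components.

**Ballistic (mirror) channel.** A phantom is a stack of non-overlapping
layers; each contributes an interface slice (field amplitude √R at its top
surface, R the intensity reflectivity in [0, 1]) and, when it scatters, a set
of volumetric sub-slices that model distributed tissue-like backscatter.
The mirror field is a coherent sum over slices j:

    E_MI(x, y; k) = Σ_j LP[ A_j(x, y) · exp(−2 τ_j) ] · exp(−i 2 k z_j) · e^{iΔφ(x,y)}

where τ_j = Σ µ·d is the single-pass optical depth accumulated above slice j
and 2kz the round-trip phase. **Attenuation convention:** µ (1/µm) is defined
so that the *field amplitude* of the round trip carries exp(−2µz); the
Beer–Lambert fits in this package are therefore performed on reconstruction
amplitude against exp(−2µz). LP is the detection aperture — a hard circular
low-pass of radius NA_det/λ_c in the spatial-frequency plane, evaluated at
the centre wavelength (achromatic-aperture approximation; the true radius
varies by ~4% across an 800–875 nm sweep). When a focal depth is configured,
each slice additionally receives the paraxial defocus pupil phase
½·k_c·(z − z_focus)·NA²·ρ².

The aperture is applied to the object structure *before* the mask phase is
attached — the mask plane is treated as conjugate to the detector. This
keeps the cancellation of Δφ between the sample and reference arms exact in
the recorded intensity, which is the mechanism STOC relies on; the trade-off
is that mask-induced diffraction at the detection aperture is not modelled.

**Crosstalk channel.** Multiply scattered light is represented statistically
rather than by solving a wave equation: each scattering layer emits circular
complex Gaussian speckle, low-passed to the detection aperture, with total
variance

    ⟨|E_OC|²⟩ = crosstalk_strength × (1 − exp(−2 µ d)),

i.e. proportional to the energy removed from the ballistic channel. The
variance is distributed uniformly over depths from the layer top to the
phantom's full axial extent — multiply scattered photons arrive with a broad
spread of delays — which is what produces the depth-uniform background in
coherent reconstructions. The speckle realization is keyed to the phase-mask
seed (masks decorrelate the physical scattering pattern), so realizations
are independent across masks and reproducible; across the sweep the speckle
is frozen by default (only the round-trip phase varies), with a per-k
redraw mode exposed since the spectral decorrelation of real tissue
crosstalk is not established. `crosstalk_strength` defaults to 0.5 for the
slab phantoms: half the removed energy reappears inside the detection
aperture — a strongly scattering sample for which coherent imaging fails
(µ underestimated ≈50%) while 64-mask STOC averaging recovers attenuation
to better than 10%.

**Detection.** I = |E_s + E_r|² with the reference A_ref·e^{iΔφ} carrying the
same mask phase (mask before the splitter). With this geometry the recorded
intensity depends on the mask only through the crosstalk realization; field-
level analyses (the coherence matrix) see the mask phase directly. Optional
Poisson shot noise and bit-depth quantisation are available and off by
default. Sweeps are sampled uniformly in wavelength, as swept lasers tune.

**Phantom defaults.** Two-layer slab: µ₁ = 2·10⁻³/µm, µ₂ = 4·10⁻³/µm,
300 µm layers, interface reflectivity 0.05, spherical defect of 180 µm
diameter and +2 contrast; volumetric backscatter fraction 0.1 with 32
axial sub-slices per layer carrying a phantom-seeded unit-mean Rayleigh
speckle texture (a lateral-uniform volume would produce a jagged coherent
axial interference profile with nothing to average over). The texture is
part of the object and fixed by the phantom seed, not regenerated per
acquisition.

## STOC averaging and metrics

Averaging operates on recorded intensities (matching both sequential
post-processing and on-chip integration; the two modes are equal by
construction and tested as such). DC removal is per-pixel along k: mean
subtraction or a zero-phase Gaussian high-pass with half-amplitude point at
0.02 × the Nyquist fringe frequency. The "fringe band" used by all residual
metrics is |fringe frequency| > 0.02 × Nyquist, separating interferometric
terms from DC/autocorrelation terms. The suppression factor compares the
fringe-band RMS of a single-exposure crosstalk residual (total minus
mirror-only from matched seeds) with that of the mask-averaged residual, so
one mask gives exactly 1. DC removal is applied after on-chip integration;
the two operations commute for the mean-subtraction variant.

## Coherence matrix and Rician fit

Pixels are linearized row-major (χ = n + m·N) and the matrix of complex
degrees of coherence γ(χ_j, χ_k) = Σ_t E*_j E_k / √(Σ|E_j|² Σ|E_k|²) is
estimated over the mask-realization ensemble, which stands in for time under
stationarity/ergodicity. Zero-energy pixels are flagged as masked (rows set
to 0) rather than reported as incoherent. ROIs are capped at K = 4096 pixels
to bound the K×K matrix. Diagonality is the mean on-diagonal |γ| over the
mean off-diagonal |γ|; a perfectly diagonal matrix reports +∞. The estimator
is verified against a brute-force pairwise loop to 1e−12.

Intensity statistics use the intensity-domain non-central exponential form
of the modified-Rician law,

    p(I) = (1/σ²) · exp(−(I + I_d)/σ²) · I₀(2√(I·I_d)/σ²),

fitted by maximum likelihood (Nelder–Mead from a method-of-moments start;
log I₀ via the exponentially scaled Bessel for stability). I_d is the
deterministic signal fraction, σ² = σ_n² the crosstalk noise variance;
I_d → 0 recovers the exponential fully-developed-speckle law. This
parameterization was chosen because the underlying description — a
deterministic phasor plus a circular random phasor — fixes the intensity
law up to these two parameters.

## Reconstruction chain

1. **Fixed-pattern filter** (optional): per-plane 2-D FFT magnitudes summed
   along depth; bins exceeding 4× a 9×9 median-filtered background outside a
   3-bin DC guard are flagged and point-symmetrised into a notch mask, so
   real images stay real after filtering.
2. **Uniform-k resampling**: cubic spline when the wavenumber spacing is
   non-uniform by more than 0.1% (always the case for uniform-λ sweeps).
3. **Depth FFT** with integer zero-padding; the positive-depth half is
   retained (nz = n_k·pad/2) and the volume is conjugated so that en-face
   fields carry the sample's own lateral/pupil phase (the retained FFT half
   holds the conjugate of the e^{−2ikz} component). Depth step
   Δz = π/(N_pad·δk).
4. **Kurtosis dispersion correction**: the analytic spectral fringe is
   multiplied by e^{iφ(κ)}, φ(κ) = Σ_{j=1..5} a_j κ^j with κ the wavenumber
   normalised to [−1, 1]; orders 2–3 are physical group-velocity dispersion,
   order 1 absorbs bulk axial displacement, orders 4–5 residuals. The
   metric is the standardised fourth moment of B-scan intensity, computed
   with a Hann spectral window — without the window the metric rewards
   redistributing the sinc-sidelobe energy of oversampled sparse peaks
   instead of compressing them. Optimisation is staged and deterministic:
   a coarse (a₂, a₃) grid, Nelder–Mead over (a₂, a₃), then a five-parameter
   polish that is kept only if it improves kurtosis by >0.5% (the order-1
   and order-4/5 directions are nearly degenerate and otherwise drift for
   negligible gain). Internally the odd monomials are orthogonalised
   against κ so that a bulk shift cannot leak into the dispersion orders.
   The converged corrector is applied to the whole volume.
5. **Split-aperture defocus**: per en-face plane the spectrum is cut into
   left/right half-apertures along f_x, each inverse-transformed, and their
   mutual displacement measured by magnitude cross-correlation with
   sub-pixel (upsampled) interpolation. A pupil phase α·ρ² displaces the
   halves by Δx = α·(u̅_R − u̅_L)·N/(2π·R²), with u̅ the *spectral-energy
   weighted* half-aperture centroids (data-driven rather than the geometric
   4R/3π, which assumes a flat spectrum). Because residual quadratic phase
   also blurs the sub-images and attenuates the measured shift, the
   estimate is refined iteratively (estimate → correct → re-measure, 3
   passes); at zero residual the estimator is unbiased, and inject–recover
   tests show <1% error. Per-depth α values are fitted linearly against
   depth; the value at the range centre converts to a Noll Z4 coefficient
   via α = 2√3·c₄.
6. **Entropy-driven Zernike correction**: coordinate descent over Noll
   coefficients of radial order 2..max (piston/tip/tilt excluded), each
   bracketed by a coarse scan over ±4 rad and refined by bounded scalar
   minimisation; cycles repeat until the per-cycle improvement is below
   tolerance. Sharpness is the Shannon entropy S = −Σ p ln p of normalised
   intensity: sharp images concentrate energy and *lower* S, so the default
   direction is minimisation (a maximisation flag exists for completeness,
   since the opposite wording also circulates). The function returns the
   estimated aberration (negation of the applied corrector), so recovered
   coefficients match injected ones in sign. Zernike polynomials use Noll
   indexing with RMS normalisation on the disk inscribed in the frequency
   plane; outside the disk the phase is zero, so every correction stage is
   unit-modulus and conserves spectral energy to 1e−9 (verified).

Multiple recorded volumes would be combined by magnitude averaging after
reconstruction; inter-volume complex registration is out of scope.

## What the synthetic generator does and does not show

The generator realises the *statistical* signature of crosstalk (delocalised
Gaussian speckle with energy-conserving variance, mask-decorrelated) and the
exact interferometric bookkeeping of the mirror channel. It does not solve
the wave equation in the medium, model polarisation, hardware timing jitter,
motion, or the k-dependence of real-tissue scattering. Passing tests
therefore demonstrate the *mechanisms* — √M averaging, coherence-matrix
diagonalisation, Rician narrowing, Beer–Lambert recovery, the √2 incoherent
resolution gain, and correct inject–recover behaviour of the computational
corrections — not quantitative agreement with any particular tissue.

## Numerical choices and problem sizes

All stochastic components are seeded through `numpy` `SeedSequence` streams
keyed by (purpose tag, user seed, mask seed, layer, depth index), so every
pipeline is bit-reproducible. The benchmark studies in `stoct.experiments`
run at 16–64 px lateral grids with 64–256 spectral samples and mask counts
up to 846 — sizes at which each study completes in seconds while the
measured exponents, ratios and recovery errors are grid-independent
properties of the method. The acceptance script repeats the averaging-law
fit over 20 independent replicates.

Degenerate inputs are rejected early with specific errors: overlapping
layers, negative µ, reflectivity outside [0, 1], non-monotonic wavenumber
axes, empty mask lists, mismatched grids, zero-energy images, fewer than
two ensemble members, fewer than 200 intensity samples for the Rician fit.

## Known limitations

* The achromatic-aperture and conjugate-mask-plane approximations above.
* The unambiguous depth range is π/(2·δk)·n_k/(n_k−1); reflectors beyond it
  alias, and the reference numerical aperture must resolve the phantom's
  lateral features for contrast metrics to be meaningful.
* The hard circular aperture makes the incoherent/coherent FWHM ratio ≈0.73
  rather than the Gaussian-pupil 1/√2 (a 3% model difference, inside the
  10% test band).
* The five-parameter phase corrector recovers orders 2–3 accurately; when
  genuine order-4/5 dispersion is small, the parsimony guard deliberately
  leaves it to be absorbed by the lower orders.
* `min_fiber_length` is exposed symbolically (it needs the source coherence
  length and core index as explicit inputs); no canonical numeric value is
  asserted for it.
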