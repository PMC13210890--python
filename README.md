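# stoct — spatio-temporal optical coherence (STOC / STOC-T) toolkit

Wide-field interferometric imaging through scattering media — full-field
swept-source OCT in particular — suffers from **optical crosstalk**: multiply
scattered light from one object point lands on many camera pixels at once,
washing out structure and producing depth profiles that no longer follow
Beer–Lambert attenuation. **STOC** suppresses this crosstalk by recording
interferograms under a rapid sequence of mutually uncorrelated spatial phase
masks Δφ(x, y) placed before the interferometer's beam splitter and averaging
the recorded intensities. Because both arms share the mask, the ballistic
(mirror-image) fringe term

&nbsp;&nbsp;&nbsp;&nbsp;I<sub>fringe</sub> = 2 A<sup>(MI)</sup> A<sup>(Ref)</sup> cos(2kz)

is mask-independent and survives the average, while crosstalk terms — whose
phases are effectively random and change from mask to mask — decay as
1/√N for N uncorrelated masks. **STOC-T** extends this volumetrically with a
wavelength-swept source: a per-pixel Fourier transform of the spectral fringe
I(x, y; k) along the wavenumber axis yields a complex volume, followed by
computational dispersion correction (kurtosis-maximising five-parameter
spectral phase), split-aperture defocus estimation, and entropy-driven
Zernike aberration correction.

The package is aimed at researchers who want to study these mechanisms
quantitatively without hardware: it couples a statistical forward model of
full-field swept-source acquisition through layered scattering phantoms to
the complete post-processing chain, plus the coherence-matrix and
modified-Rician diagnostics used to quantify crosstalk suppression, and the
closed-form design calculators (guided-mode count N ≈ 2π²a²NA²/λ², √N
attenuation, depth of field λ/NA², sweep timing, dataset sizing).

## Worked example

Design numbers for the reference step-index multimode fiber
(a = 25 µm, NA = 0.22, λ = 840 nm) and acquisition budget:

```
$ stoct calc modes
N = 846.2 (≈ 846 modes), sqrt(N) = 29.09

$ stoct calc timing --volumes 32
{
  "per_volume_ms": 8.620689655172413,
  "total_ms": 285.1620689655172,
  "data_gb": 8.589934592
}
```

So the fiber supports ≈846 transverse modes, giving an expected crosstalk
attenuation of √846 ≈ 29; one 800→875 nm sweep at 8700 nm/s takes 8.6 ms and
32 volumes of 512³ 16-bit voxels occupy 8.59 GB.

The flagship simulation: a two-layer scattering slab (µ₁ = 3·10⁻³/µm,
µ₂ = 6·10⁻³/µm) imaged with and without STOC modulation, then fitted with
exp(−2µz):

```python
from stoct import experiments as ex
print(ex.two_layer_attenuation_recovery(seed=1, n_masks=64))
```

```
{'mu_true': 0.003, 'mu_stoc': 0.00281, 'mu_coherent': 0.001405,
 'stoc_error': 0.0633, 'coherent_error': 0.5315}
```

Averaging 64 uncorrelated masks recovers the ground-truth attenuation within
6%; the coherent (flat-mask) reconstruction is dominated by a depth-uniform
crosstalk background and underestimates µ by 53% — the anomalously flat
depth profile characteristic of crosstalk-limited full-field OCT.

The full pipeline is also scriptable:

```bash
stoct simulate --phantom two_layer_slab_with_defect --masks 64 \
      --mask-kind membrane --mode sequential --seed 7 --out vol.h5
stoct average --in 'vol_mask*.h5' --dc highpass --out avg.h5 --report report.json
stoct reconstruct --in avg.h5 --pad 2 --dispersion kurtosis --out recon.h5
stoct gmatrix --phantom plane_behind_diffuser --roi 16x16+8+8 --out G.h5
stoct run --config demo.yaml --out results/
```

Library surface: `stoct.forward` (phantoms, phase masks, interferogram
simulation), `stoct.stoc` (mask averaging, DC removal, suppression metrics),
`stoct.coherence` (G-matrix, diagonality, Rician MLE), `stoct.recon` /
`stoct.dispersion` / `stoct.aberration` (depth FFT, fixed-pattern filter,
kurtosis / split-aperture / entropy corrections), `stoct.design`
(calculators), `stoct.experiments` (canned benchmark studies).

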