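"""Scattering coherence matrix and speckle intensity statistics.

The degree of spatial coherence between detector pixels diagnoses optical
crosstalk: multiply scattered light correlates distant pixels, while a
well-suppressed (STOC) acquisition leaves each pixel correlated only with
itself.  Pixels (x_n, y_m) are linearized as χ = n + m·N and the K×K matrix
of complex degrees of coherence

    γ(χ_j, χ_k) = ⟨E*(χ_j) E(χ_k)⟩ / √(⟨|E(χ_j)|²⟩ ⟨|E(χ_k)|²⟩)

is estimated over an ensemble of field realizations (the mask-realization
ensemble stands in for time, assuming stationarity and ergodicity).

Intensity statistics of the reconstructed image follow a modified-Rician
law — the coherent superposition of a deterministic signal vector I_d and a
circular random crosstalk vector of variance σ_n²:

    p(I) = (1/σ²) · exp(−(I + I_d)/σ²) · I₀(2√(I·I_d)/σ²),

which reduces to the exponential (fully developed speckle) law as I_d → 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special

DEFAULT_K_LIMIT = 4096  # largest K = |ROI| accepted by build_G


@dataclasses.dataclass(frozen=True)
class PixelLinearization:
    """Bijective map between lattice pixels (n, m) and linear index χ = n + m·N."""

    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dims must be >= 1")

    @property
    def size(self) -> int:
        return self.nx * self.ny

    def forward(self, n: int, m: int) -> int:
        if not (0 <= n < self.nx and 0 <= m < self.ny):
            raise ValueError("pixel outside grid")
        return n + m * self.nx

    def inverse(self, chi: int) -> tuple[int, int]:
        if not (0 <= chi < self.size):
            raise ValueError("linear index outside grid")
        return chi % self.nx, chi // self.nx


def linearize(nx: int, ny: int) -> PixelLinearization:
    return PixelLinearization(nx=nx, ny=ny)


@dataclasses.dataclass(frozen=True)
class CoherenceMatrix:
    """K×K matrix of complex degrees of coherence over linearized pixels.

    ``masked`` flags zero-energy pixels whose rows/columns were set to 0 —
    data masking, not genuine loss of coherence.
    """

    gamma: np.ndarray
    roi: tuple[slice, slice] | np.ndarray | None = None
    masked: np.ndarray | None = None
    tau: int = 0
    k_index: int | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("gamma must be square")
        if not np.allclose(g, g.conj().T, atol=1e-12):
            raise ValueError("gamma must be Hermitian")
        if np.any(np.abs(g) > 1.0 + 1e-9):
            raise ValueError("|gamma| must not exceed 1")

    @property
    def K(self) -> int:
        return self.gamma.shape[0]


def _roi_fields(fields: np.ndarray, roi) -> np.ndarray:
    """Extract (T, K) ensemble matrix from (T, ny, nx) frames and an ROI."""
    if roi is None:
        return fields.reshape(fields.shape[0], -1)
    if isinstance(roi, tuple) and len(roi) == 2 and all(isinstance(s, slice) for s in roi):
        sub = fields[:, roi[0], roi[1]]
        return sub.reshape(fields.shape[0], -1)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != fields.shape[1:]:
        raise ValueError("boolean ROI must match the frame grid")
    return fields[:, roi]


def build_G(
    fields: np.ndarray,
    roi=None,
    tau: int = 0,
    k_index: int | None = None,
    k_limit: int = DEFAULT_K_LIMIT,
) -> CoherenceMatrix:
    """Estimate the coherence matrix from an ensemble of complex frames.

    Parameters
    ----------
    fields : array (T, ny, nx), complex
        One frame per mask realization (T >= 2; >= 8 recommended).
    roi : pair of slices, boolean mask, or None
        Pixel subset; K = number of ROI pixels, row-major (χ = n + m·N).
    tau : int
        Ensemble lag; ``gamma[j,k]`` correlates member t with t+tau.
    """
    fields = np.asarray(fields)
    if fields.ndim != 3:
        raise ValueError("fields must be (T, ny, nx)")
    if fields.shape[0] < 2:
        raise ValueError("need at least 2 ensemble members")
    x = _roi_fields(fields, roi)
    if x.shape[1] == 0:
        raise ValueError("empty ROI")
    if x.shape[1] > k_limit:
        raise ValueError(f"ROI has {x.shape[1]} pixels, above the K limit {k_limit}")
    if tau:
        a, b = x[:-tau], x[tau:]
    else:
        a = b = x
    cross = a.conj().T @ b
    if tau:
        # symmetrise the lagged estimate so gamma stays Hermitian
        cross = 0.5 * (cross + cross.conj().T)
    energy_a = np.sum(np.abs(x) ** 2, axis=0)
    norm = np.sqrt(np.outer(energy_a, energy_a))
    masked = energy_a == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(norm > 0, cross / np.where(norm > 0, norm, 1.0), 0.0)
    gamma[masked, :] = 0.0
    gamma[:, masked] = 0.0
    # clip micro-overshoot from rounding
    mag = np.abs(gamma)
    over = mag > 1.0
    if np.any(over):
        gamma[over] /= mag[over]
    gamma = 0.5 * (gamma + gamma.conj().T)
    return CoherenceMatrix(gamma=gamma, roi=roi, masked=masked, tau=tau, k_index=k_index)


def diagonality(G: CoherenceMatrix) -> float:
    """Diagonal dominance: mean |γ| on the (unmasked) diagonal divided by the
    mean |γ| off the diagonal.  Returns +inf for a perfectly diagonal matrix."""
    if G.K < 2:
        raise ValueError("need K >= 2")
    keep = ~G.masked if G.masked is not None else np.ones(G.K, dtype=bool)
    if not np.any(keep):
        raise ValueError("all pixels are masked")
    mag = np.abs(G.gamma)[np.ix_(keep, keep)]
    n = mag.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 unmasked pixels")
    diag = np.mean(np.diag(mag))
    off = (mag.sum() - np.trace(mag)) / (n * n - n)
    if off == 0:
        return np.inf
    return float(diag / off)


# ---------------------------------------------------------------------------
# modified-Rician intensity statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RicianFit:
    """Maximum-likelihood fit of the modified-Rician intensity law.

    i_det : deterministic (undistorted-signal) intensity fraction I_d
    sigma_n2 : crosstalk noise variance σ_n²
    """

    i_det: float
    sigma_n2: float
    loglik: float
    n_samples: int
    converged: bool = True
    message: str = ""


def _rician_negloglik(params: np.ndarray, i: np.ndarray) -> float:
    i_d, s2 = params
    if s2 <= 0 or i_d < 0:
        return np.inf
    # log I0(x) computed via the exponentially scaled Bessel for stability
    x = 2.0 * np.sqrt(i * i_d) / s2
    log_i0 = np.log(special.ive(0, x)) + x
    ll = -np.log(s2) - (i + i_d) / s2 + log_i0
    return -float(np.sum(ll))


def fit_rician(intensities: np.ndarray, roi=None) -> RicianFit:
    """Fit p(I) = (1/σ²)·exp(−(I+I_d)/σ²)·I₀(2√(I·I_d)/σ²) by maximum
    likelihood to a sample of normalized intensities I/⟨I⟩.

    Initialised from the method of moments (mean = I_d + σ²,
    var = σ⁴ + 2 I_d σ²); the degenerate I_d → 0 limit is the exponential
    (fully developed speckle) law.
    """
    i = np.asarray(intensities, dtype=float)
    if roi is not None:
        i = i[np.asarray(roi, dtype=bool)] if i.ndim > 1 else i
    i = i.ravel()
    if i.size < 200:
        raise ValueError("need at least 200 intensity samples")
    if np.any(i < 0):
        raise ValueError("intensities must be non-negative")
    m, v = float(np.mean(i)), float(np.var(i))
    disc = max(m * m - v, 0.0)
    s0 = m - np.sqrt(disc)
    s0 = min(max(s0, 1e-6 * m if m > 0 else 1e-6), m)
    id0 = max(m - s0, 0.0)
    res = optimize.minimize(
        _rician_negloglik,
        x0=np.array([id0, s0]),
        args=(i,),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    i_d, s2 = res.x
    return RicianFit(
        i_det=float(max(i_d, 0.0)),
        sigma_n2=float(s2),
        loglik=-float(res.fun),
        n_samples=i.size,
        converged=bool(res.success),
        message=str(res.message),
    )
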