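import numpy as np
import pytest

from stoct import OpticalConfig, generate_phase_mask


@pytest.fixture
def small_config():
    """Tiny grid for fast unit tests."""
    return OpticalConfig(
        nx=32, ny=32, n_k=64, lambda_start=800.0, lambda_end=875.0,
        na_det=0.3, na_ill=0.1, pixel_pitch_obj=2.0, ref_amplitude=10.0,
    )


@pytest.fixture
def spectral_config():
    """Grid with enough spectral samples for depth-resolved work."""
    return OpticalConfig(
        nx=32, ny=32, n_k=256, lambda_start=800.0, lambda_end=875.0,
        na_det=0.3, na_ill=0.1, pixel_pitch_obj=2.0, ref_amplitude=10.0,
    )


@pytest.fixture
def flat_mask(small_config):
    return generate_phase_mask(small_config, "flat", 0)


def band_limited_point_grid(shape, seed, n_points=40, band=0.35):
    """Sparse complex point-target image, band-limited inside the pupil."""
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
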