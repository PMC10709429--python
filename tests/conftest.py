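"""Shared fixtures: small synthetic scenes and speckle image pairs."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.ndimage import fourier_shift

from ringflow import scene


@pytest.fixture(scope="session")
def default_scene():
    """Asymmetric closure scene at the default study conditions."""
    cfg = scene.SceneConfig()
    return scene.build_scene(cfg)


@pytest.fixture(scope="session")
def clean_ring_config():
    """Noiseless, background-free ring scene for exact-recovery checks."""
    return scene.SceneConfig(noise_sigma=0.0, background=0.0)


@pytest.fixture(scope="session")
def speckle_pair_factory():
    """Factory producing (frame_a, frame_b) with a known rigid shift.

    The base image is band-limited speckle (Gaussian-smoothed white
    noise); frame_b is frame_a circularly shifted by ``(dy, dx)`` via
    Fourier interpolation, so the shift is exact everywhere including
    sub-pixel components. Gaussian noise is added at the requested SNR.
    """
    def make(shift, snr=10.0, size=160, seed=1, noise_seed=2):
        rng = np.random.default_rng(seed)
        base = ndimage.gaussian_filter(rng.normal(size=(size, size)), 1.5)
        shifted = np.fft.ifftn(fourier_shift(np.fft.fftn(base), shift)).real
        nrng = np.random.default_rng(noise_seed)
        sigma = base.std() / snr if snr and np.isfinite(snr) else 0.0
        a = base + nrng.normal(0, sigma, base.shape) if sigma else base
        b = shifted + nrng.normal(0, sigma, base.shape) if sigma else shifted
        return a, b

    return make
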