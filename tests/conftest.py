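import numpy as np
import pytest

import sfex


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def clean_benchmark():
    """Noise-free shipped benchmark scene (session-cached; read-only)."""
    return sfex.default_benchmark_scene(psnr=None)


@pytest.fixture(scope="session")
def noisy_benchmark():
    """Benchmark scene at 25 dB PSNR (session-cached; read-only)."""
    return sfex.default_benchmark_scene(psnr=25.0, seed=7)


def straight_line_image(shape=(64, 64), row=32, col_span=(10, 54),
                        sigma=0.667, peak=100.0):
    """A single horizontal blurred line; returns (image, skeleton_mask)."""
    from scipy.ndimage import gaussian_filter
    skel = np.zeros(shape, dtype=bool)
    skel[row, col_span[0]:col_span[1]] = True
    img = gaussian_filter(skel.astype(float), sigma)
    img *= peak / img.max()
    return img, skel
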