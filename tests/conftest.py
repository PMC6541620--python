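import numpy as np
import pytest

from cellquant.synthetic import CellPhantomSpec, make_cell_image


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom with its ground truth."""
    spec = CellPhantomSpec(noise_sd_frac=0.0)
    return make_cell_image(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom at 5% Gaussian noise."""
    spec = CellPhantomSpec(noise_sd_frac=0.05, seed=7)
    return make_cell_image(spec)


def rasterized_disk(radius: int, size: int | None = None) -> np.ndarray:
    size = size or (2 * radius + 21)
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius * radius
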