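import numpy as np
import pytest

from paintseg.synthfix import SceneParams, generate_scene


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Rasterized disk x^2 + y^2 <= r^2 centered in a padded canvas."""
    n = 2 * radius + 1 + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_scene():
    """Low-noise scene with 5 isolated cells, one nucleus each."""
    return generate_scene(SceneParams(size=192, n_cells=5, noise_sigma=60.0), seed=11)


@pytest.fixture(scope="session")
def degraded_scene():
    """Scene with planted multi-nucleate merges and anucleate fragments."""
    return generate_scene(
        SceneParams(size=512, n_cells=10, multi_nucleate_fraction=0.2, fragment_fraction=0.3),
        seed=3,
    )
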