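import numpy as np
import pytest

import craniomorph as cm


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Default full head phantom (brain, skull, fat, muscle, face)."""
    return cm.make_phantom(cm.preset_spec("ellipsoid"))


@pytest.fixture(scope="session")
def sphere_phantom():
    return cm.make_phantom(cm.preset_spec("sphere"))


@pytest.fixture(scope="session")
def two_density_phantom():
    return cm.make_phantom(cm.preset_spec("two-density"))


@pytest.fixture(scope="session")
def shell_5mm():
    """Minimal sphere-shell phantom with a 5 mm skull wall."""
    spec = cm.shell_spec(5.0)
    labels, t1, ct, truth = cm.make_phantom(spec)
    return labels, t1, ct, truth


def random_binary_mask(rng, max_side=32, p=0.15):
    shape = tuple(rng.integers(4, max_side + 1, size=3))
    data = (rng.random(shape) < p).astype(np.uint8)
    return cm.BinaryMask(data=data)


def random_blob_mask(rng, side=16):
    """A connected-ish random blob (a few dilated seed points)."""
    from scipy import ndimage

    data = np.zeros((side, side, side), dtype=bool)
    n_seeds = int(rng.integers(1, 4))
    for _ in range(n_seeds):
        x, y, z = rng.integers(2, side - 2, size=3)
        data[x, y, z] = True
    data = ndimage.binary_dilation(data, iterations=int(rng.integers(1, 4)))
    return cm.BinaryMask(data=data.astype(np.uint8))
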