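import numpy as np
import pytest

from lesionfill import PhantomSpec, LesionSpec, generate_phantom, generate_lesion_mask


def box_mask(shape, lo, hi):
    m = np.zeros(shape, bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


@pytest.fixture
def small_phantom():
    """A 36-cube textured, noisy phantom with a seeded lesion mask."""
    spec = PhantomSpec(shape=(36, 36, 36), noise_sigma=2.0, seed=7)
    image, labels, brain = generate_phantom(spec)
    mask = generate_lesion_mask(labels, brain, LesionSpec(n_blobs=2, radius_range=(1.5, 2.5), seed=8))
    return image, labels, brain, mask
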