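import numpy as np
import pytest

from axotrace import phantoms as ph


@pytest.fixture(scope="session")
def small_retina_spec():
    """Compact noise-free retina phantom spec used across detector tests."""
    return ph.RetinaPhantomSpec(
        image_size_px=(512, 512), n_cells=50, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_retina_phantom(small_retina_spec):
    return ph.generate_retina_phantom(small_retina_spec, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140917)


def random_section(rng, shape=(20, 20), roi_p=0.5, bg_p=0.3):
    """A random SC section with disjoint random ROI and reference masks."""
    from axotrace.colliculus import SCSection

    pixels = rng.uniform(0, 100, shape)
    roi = rng.random(shape) < roi_p
    bg = ~roi & (rng.random(shape) < bg_p)
    if not roi.any():
        roi[shape[0] // 2, shape[1] // 2] = True
        bg[shape[0] // 2, shape[1] // 2] = False
    if not bg.any():
        free = np.argwhere(~roi)
        bg[tuple(free[0])] = True
    return SCSection(pixels=pixels, roi_mask=roi, background_roi=bg)
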