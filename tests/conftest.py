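import numpy as np
import pytest

from glandseg.synthetic import GlandSpec, TissueSpec, generate_tile


@pytest.fixture(scope="session")
def small_tile():
    """One noisy 256 px tile with a single well-formed gland."""
    spec = TissueSpec(
        image_size=(256, 256),
        gland_specs=[GlandSpec("well_formed", (128, 128), size=40, n_nuclei=8)],
        rng_seed=11,
    )
    return generate_tile(spec)


@pytest.fixture(scope="session")
def clean_tile():
    """Noise-free, unquantized tile: exact Beer-Lambert forward model."""
    spec = TissueSpec(
        image_size=(192, 192),
        gland_specs=[GlandSpec("well_formed", (96, 96), size=35, n_nuclei=6)],
        ccd_sigma=0.0,
        stain_intensity_cv=0.0,
        stroma_texture=0.0,
        quantize=False,
        rng_seed=7,
    )
    return generate_tile(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
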