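import numpy as np
import pytest

from y90dosim.phantom import LesionSpec, PhantomConfig, generate_phantom


def small_phantom_config(**overrides) -> PhantomConfig:
    """32^3 phantom at 4 mm with one 3.6 cm and one 2.4 cm lesion, noise off."""
    defaults = dict(
        shape=(32, 32, 32),
        spacing_mm=4.0,
        liver_semiaxes_mm=(56.0, 50.0, 46.0),
        liver_center_mm=(62.0, 62.0, 62.0),
        perfused_semiaxes_mm=(36.0, 36.0, 34.0),
        perfused_offset_mm=(14.0, 0.0, 0.0),
        lesions=[
            LesionSpec((76.0, 62.0, 62.0), 3.6, "big"),
            LesionSpec((76.0, 94.0, 62.0), 2.4, "mid"),
        ],
        tumor_to_normal=5.0,
        poisson_noise=False,
        psf_fwhm_mm=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture
def noise_free_phantom():
    return generate_phantom(small_phantom_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
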