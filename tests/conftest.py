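import numpy as np
import pytest

from vhiseg.core import ImageVolume, RegionMask
from vhiseg.phantom import LesionSpec, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def lesion_case():
    """Noise-free phantom with one high-contrast spherical lesion."""
    config = PhantomConfig(
        lesion_specs=[LesionSpec((48, 30, 6), 8.0, 2.0)],
        n_vessels=0,
        noise_sd=0.0,
        seed=3,
    )
    return generate_phantom(config)


@pytest.fixture(scope="session")
def vessel_case():
    """Noisy phantom with a lesion and bright vessels crossing the bone."""
    config = PhantomConfig(
        lesion_specs=[LesionSpec((48, 30, 6), 7.0, 2.0)],
        n_vessels=3,
        noise_sd=2.0,
        seed=11,
    )
    return generate_phantom(config)


def make_mask(data, spacing=(1.0, 1.0, 1.0), identifier="mask"):
    return RegionMask(np.asarray(data, dtype=bool), spacing, identifier)


def make_volume(data, spacing=(1.0, 1.0, 1.0), identifier="vol"):
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, identifier)
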