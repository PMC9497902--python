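import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hsiph import (DEFAULT_GRID, PhantomSpec, generate_phantom_hypercube,
                   generate_spectra_table, preset_reduced_model)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def phantom():
    """One default phantom scene with its ground truth."""
    return generate_phantom_hypercube(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom():
    """32x32 scene used by the pixel-loop oracles."""
    spec = PhantomSpec(shape=(32, 32), ellipse_axes=(11.0, 13.0),
                       ph_gradient=(4.6, 6.3), seed=21)
    return generate_phantom_hypercube(spec)


@pytest.fixture(scope="session")
def linear_table():
    """Noiseless spectra table generated from the preset 12-wavelength rule."""
    return generate_spectra_table(12, preset_reduced_model(), noise_sd=0.0,
                                  seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
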