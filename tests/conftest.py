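"""Shared fixtures: small seeded phantoms and acquisition schemes."""

import numpy as np
import pytest

from dwifit import phantom
from dwifit.gradients import GradientTable
from dwifit.sphere import uniform_sphere_directions


@pytest.fixture(scope="session")
def scheme32() -> GradientTable:
    """2 b=0 + 30 b=1000 s/mm² single-shell scheme (prefix of the default)."""
    return phantom.default_scheme().subset(np.r_[0:2, 18:48])


@pytest.fixture(scope="session")
def tensor_phantom_clean(scheme32):
    """Noise-free single-tensor 6³ phantom (exact-model identifiability)."""
    spec = phantom.SimSpec(
        grid=(6, 6, 6), n_tensors_choices=(1,), seed=11, scheme=scheme32
    )
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def multi_tensor_phantom_clean(scheme32):
    """Noise-free multi-tensor 6³ phantom (1-3 crossing compartments)."""
    spec = phantom.SimSpec(grid=(6, 6, 6), seed=12, scheme=scheme32)
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def kurtosis_phantom_clean():
    spec = phantom.SimSpec(grid=(4, 4, 4), seed=5)
    return phantom.make_kurtosis_phantom(spec)


@pytest.fixture(scope="session")
def noddi_phantom_clean():
    spec = phantom.SimSpec(grid=(4, 4, 4), seed=7)
    return phantom.make_noddi_phantom(spec)


@pytest.fixture(scope="session")
def dirs30():
    return uniform_sphere_directions(30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
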