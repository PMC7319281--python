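import numpy as np
import pytest

from flute.basis import BasisSpec, CoefficientSet


@pytest.fixture
def rng():
    return np.random.default_rng(20200626)


def random_coeff_set(rng, n, K, scale=1.0):
    return CoefficientSet(scale * rng.standard_normal((n, K)), BasisSpec("fourier", K))


@pytest.fixture
def coeff_pair(rng):
    """A small (X, Y) coefficient pair on K=4 / L=3 Fourier bases."""
    return random_coeff_set(rng, 10, 4), random_coeff_set(rng, 10, 3)
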