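import numpy as np
import pytest

from crumbflow import FoamParams, generate_foam
from crumbflow.stencil import D2Q9, D3Q27


@pytest.fixture(params=[2, 3], ids=["d2q9", "d3q27"])
def stencil(request):
    return D2Q9 if request.param == 2 else D3Q27


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_foam():
    """A 96x96 crumb-like foam with an open, percolating pore space."""
    params = FoamParams(
        shape=(96, 96), target_porosity=0.70, seed=3,
        bubble_radius_median_mm=0.15, perforation_probability=0.7,
    )
    return generate_foam(params)
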