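import numpy as np
import pytest

from knotcost import canonical_knot_polygons


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def knot_polygons():
    return canonical_knot_polygons()
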