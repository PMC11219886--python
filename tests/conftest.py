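import numpy as np
import pytest

from remcpm.connectome import Parcellation, parcellation_from_sizes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_parcellation():
    """20 nodes over 4 networks — small enough for exhaustive oracles."""
    return parcellation_from_sizes(
        {"DMN": 6, "VIS": 5, "CON": 5, "SUB": 4})


@pytest.fixture
def ten_net_parcellation():
    """46 nodes covering all ten networks (1035 edges)."""
    from helpers import REDUCED_SIZES

    return parcellation_from_sizes(REDUCED_SIZES)
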