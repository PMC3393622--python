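import random

import pytest

from treespectra.exchange import smallest_exchange_pair


@pytest.fixture(scope="session")
def glap_exchange_pair():
    """The smallest subtree pair with the generalized-Laplacian exchange
    property, found by exhaustive search (17 leaves)."""
    res = smallest_exchange_pair("generalized_laplacian", 17)
    assert res is not None
    return res


@pytest.fixture()
def rng():
    return random.Random(20260929)
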