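import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def canonical_scheme():
    from dunbargraph import LayerScheme

    return LayerScheme()


@pytest.fixture
def four_layer_scheme():
    from dunbargraph import LayerScheme

    return LayerScheme((5, 15, 50, 150))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
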