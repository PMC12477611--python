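import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_bundle():
    """500-spot 2-domain RNA+ADT bundle shared across training tests."""
    from sofusion.synthetic import make_smoke_bundle

    return make_smoke_bundle(seed=0)
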