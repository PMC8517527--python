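import numpy as np
import pytest

from mfuseg import PhantomConfig, NetworkSpec, build_mfunet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_net():
    """A width-reduced MFU-net shared by read-only forward-pass tests."""
    return build_mfunet(NetworkSpec(base_width=4), seed=11)


@pytest.fixture
def phantom_pair():
    from mfuseg import generate_phantom

    return generate_phantom(PhantomConfig(seed=5))
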