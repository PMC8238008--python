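import numpy as np
import pytest

from kinomics.simulate import SimConfig, gen_genome


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic genome shared across read-only tests."""
    return gen_genome(SimConfig(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
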