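import numpy as np
import pytest

from retveseg import PhantomSpec, generate, segment


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom with the default spec, reused across test modules."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def default_result(default_phantom):
    """The full pipeline run on the default phantom."""
    return segment(default_phantom.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
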