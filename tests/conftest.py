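import numpy as np
import pytest

from mpctrace.fia_annotation import load_compound_library


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mid(rng, n):
    """A random valid MID over M+0..M+n."""
    x = rng.dirichlet(np.ones(n + 1))
    return x / x.sum()
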