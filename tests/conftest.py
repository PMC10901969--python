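import numpy as np
import pytest

from vasotone.config import default_params


@pytest.fixture(scope="session")
def bundle():
    """Shipped fitted parameter set (vessels group 1)."""
    return default_params()


@pytest.fixture(scope="session")
def net(bundle):
    return bundle.network


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
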