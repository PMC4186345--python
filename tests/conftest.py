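import numpy as np
import pytest
from hypothesis import settings

from maskfield import build_catalog, init_weights

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog_m4():
    return build_catalog(4, lmax=4, redundancy=1)


@pytest.fixture(scope="session")
def catalog_m2():
    return build_catalog(2, lmax=2, redundancy=1)


@pytest.fixture()
def weights_m4(catalog_m4):
    return init_weights(catalog_m4, rng=np.random.default_rng(0))
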