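import numpy as np
import pytest

from trioburden import make_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(n_genes=8, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
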