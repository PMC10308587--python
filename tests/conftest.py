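import numpy as np
import pytest

import omegafq as o


@pytest.fixture(scope="session")
def silver_material():
    return o.silver()


@pytest.fixture(scope="session")
def tip55():
    return o.tip_cluster()


@pytest.fixture()
def dimer():
    return o.dimer()


@pytest.fixture()
def square():
    return o.square4()


@pytest.fixture()
def molecule3():
    return o.generate_synthetic_tensors(o.SyntheticRamanSet(n_modes=3), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
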