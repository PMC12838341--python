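import numpy as np
import pytest

from cellvae import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def group_configs():
    return synthgen.default_group_configs(2.0)


@pytest.fixture(scope="session")
def tiny_dataset(group_configs):
    control, treated = group_configs
    return synthgen.generate_dataset(control, treated, n_per_group=8,
                                     size=64, seed=7)


@pytest.fixture(scope="session")
def tiny_stack(tiny_dataset):
    return np.stack(tiny_dataset.images)
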