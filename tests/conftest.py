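import numpy as np
import pytest

from dfcn.phantom import PhantomConfig, generate_phantom_case


@pytest.fixture(scope="session")
def small_phantom_cfg():
    return PhantomConfig(image_size=(64, 64), slices_per_case=(3, 4))


@pytest.fixture(scope="session")
def small_case(small_phantom_cfg):
    return generate_phantom_case(small_phantom_cfg, case_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
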