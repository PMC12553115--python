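import numpy as np
import pytest

from psmem import GeneratorParams, generate_design, generate_patterns


@pytest.fixture(scope="session")
def design():
    return generate_design(seed=7, group="placebo")


@pytest.fixture(scope="session")
def params():
    return GeneratorParams(seed=7)


@pytest.fixture(scope="session")
def pattern_set(design, params):
    return generate_patterns(design, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
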