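import numpy as np
import pytest

from bayesmt import bygren_ratio_estimates, bygren_table1


@pytest.fixture(scope="session")
def table1():
    return bygren_table1()


@pytest.fixture(scope="session")
def table1_rows():
    return bygren_ratio_estimates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20190513)
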