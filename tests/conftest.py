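import numpy as np
import pytest

from ipm import synthetic_data as sd


@pytest.fixture(scope="session")
def default_spec():
    return sd.make_default_process(seed=7)


@pytest.fixture(scope="session")
def oracle_chain():
    return sd.make_oracle_chain()


@pytest.fixture(scope="session")
def oracle():
    return sd.analytic_chain_oracle(sd.make_oracle_chain(), "imp")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
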