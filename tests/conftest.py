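import numpy as np
import pytest

from augerdose import (
    load_attenuation_table,
    load_cu64_scheme,
    load_stopping_power_table,
)


@pytest.fixture(scope="session")
def sp_table():
    return load_stopping_power_table()


@pytest.fixture(scope="session")
def att_table():
    return load_attenuation_table()


@pytest.fixture(scope="session")
def scheme():
    return load_cu64_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
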