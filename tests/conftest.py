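import numpy as np
import pytest

from indivobs import (
    AgeSource,
    SDTable,
    generate_fixture_stimuli,
    load_basis_tables,
)


@pytest.fixture(scope="session")
def basis():
    return load_basis_tables()


@pytest.fixture(scope="session")
def five_matches():
    return generate_fixture_stimuli("five_matches")


@pytest.fixture(scope="session")
def step2():
    return SDTable.step2()


@pytest.fixture(scope="session")
def uniform_ages():
    return AgeSource.from_uniform(20.0, 60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
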