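import numpy as np
import pytest

from saltmix.lattice import ChemicalPotentials, InteractionParams


@pytest.fixture
def J3() -> InteractionParams:
    return InteractionParams(3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230131)


def mu(m1, m2) -> ChemicalPotentials:
    return ChemicalPotentials(m1, m2)
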