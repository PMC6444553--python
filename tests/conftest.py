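import pytest

from dualfep.synthetic_data import gen_toy_ligand_pair, gen_toy_parameters


@pytest.fixture(scope="session")
def toy_pair():
    """A superposed 5-common-atom ligand pair with 3/2 unique substituent atoms."""
    return gen_toy_ligand_pair(5, 3, 2, seed=0)


@pytest.fixture(scope="session")
def toy_params(toy_pair):
    return gen_toy_parameters(*toy_pair)
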