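import pytest
from hypothesis import settings

from pyrocast.chem_core import parse_molecule
from pyrocast.ms_spectra import load_fixture_spectrum
from pyrocast.synthetic_data import generate_flavour_set, make_case

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def pentanedione():
    return parse_molecule("CCC(=O)C(=O)C")


@pytest.fixture(scope="session")
def pentanedione_spectrum():
    return load_fixture_spectrum("pentanedione")


@pytest.fixture(scope="session")
def small_flavours():
    return generate_flavour_set(12, seed=5)


@pytest.fixture(scope="session")
def synthetic_cases(small_flavours):
    return [
        make_case(mol, f"f{i:03d}", seed=200 + i)
        for i, mol in enumerate(small_flavours)
    ]
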