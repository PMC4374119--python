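import random

import pytest

from wikichem.fingerprint import load_default_dictionary
from wikichem.molgraph import MolecularGraph, parse_smiles
from wikichem.synthgen import GenConfig, random_molecule


@pytest.fixture(scope="session")
def dictionary():
    return load_default_dictionary()


def mol(smiles: str) -> MolecularGraph:
    """Parse or fail the test with a readable message."""
    graph = parse_smiles(smiles)
    assert isinstance(graph, MolecularGraph), f"{smiles!r} -> {graph}"
    return graph


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture(scope="session")
def random_molecules():
    """200 deterministic random molecules shared across property tests."""
    r = random.Random(99)
    config = GenConfig(seed=99, atom_budget=(1, 12), ring_probability=0.35)
    return [random_molecule(config, r) for _ in range(200)]
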