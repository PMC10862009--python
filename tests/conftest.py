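import numpy as np
import pytest

from helixgraft.structure_io import (AtomRecord, Ensemble, PolymerStructure,
                                     Residue)
from helixgraft.synthetic_data import (build_ideal_helix, build_toy_scaffold,
                                       build_two_helix_bundle)


@pytest.fixture(scope="session")
def ideal_helix20():
    return build_ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def toy_scaffold():
    return build_toy_scaffold()


@pytest.fixture(scope="session")
def bundle():
    return build_two_helix_bundle()


def random_structure(rng: np.random.Generator, n_res: int = 5,
                     chain_id: str = "A") -> PolymerStructure:
    """Small random-coordinate structure for round-trip style tests."""
    residues = []
    names = ["ALA", "GLY", "SER", "LEU", "TRP"]
    for i in range(n_res):
        res = Residue(chain_id, i + 1, names[i % len(names)])
        for atom, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            res.atoms.append(AtomRecord(atom, elem,
                                        rng.uniform(-40, 40, 3).round(3)))
        residues.append(res)
    return PolymerStructure({chain_id: residues})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
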