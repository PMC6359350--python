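import numpy as np
import pytest

from ssv.fixtures import ToySpec, make_toy_chain, make_toy_structure

CLASS_SET_POOL = [
    frozenset({"hydrophobic"}),
    frozenset({"negative", "acceptor"}),
    frozenset({"positive", "donor"}),
    frozenset({"sulfur"}),
    frozenset({"donor", "acceptor"}),
    frozenset({"aromatic"}),
    frozenset({"acceptor"}),
    frozenset({"donor"}),
    frozenset({"neutral"}),
]


def random_atom_spec(n_atoms: int, seed: int, extent: float = 6.0):
    """(class-set, coords) list usable by both the toy builder and the oracle."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_atoms):
        classes = CLASS_SET_POOL[rng.integers(len(CLASS_SET_POOL))]
        atoms.append((classes, tuple(rng.uniform(-extent, extent, size=3))))
    return atoms


@pytest.fixture(scope="session")
def toy_chain():
    """A 20-residue chain covering every canonical amino acid type."""
    return make_toy_chain("ACDEFGHIKLMNPQRSTVWY", seed=3)


@pytest.fixture(scope="session")
def small_chain():
    return make_toy_chain("ACDEFGHIK", seed=7, structure_id="smallchain")


@pytest.fixture()
def two_atom_structure():
    """Two purely hydrophobic atoms 3.05 Å apart (worked signature example)."""
    spec = ToySpec(
        atoms=[
            (frozenset({"hydrophobic"}), (0.0, 0.0, 0.0)),
            (frozenset({"hydrophobic"}), (3.05, 0.0, 0.0)),
        ]
    )
    return make_toy_structure(spec)
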