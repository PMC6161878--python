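import numpy as np
import pytest

from snvloci import structure_features as sf
from snvloci.synthetic_fixtures import make_helix_structure


@pytest.fixture(scope="session")
def helix_pdb() -> str:
    return make_helix_structure(20, seed=1)


@pytest.fixture(scope="session")
def helix(helix_pdb) -> sf.Structure:
    return sf.parse_structure(helix_pdb, "helix")


def ca_only_structure(coords, names=None) -> sf.Structure:
    """Structure with one CA atom per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    residues = [
        sf.Residue(
            name=(names[i] if names else "ALA"),
            number=i + 1,
            chain_id="A",
            atoms=[sf.Atom("CA", "C", coords[i])],
        )
        for i in range(len(coords))
    ]
    return sf.Structure(id="points", chains=[sf.Chain(name="A", residues=residues)])
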