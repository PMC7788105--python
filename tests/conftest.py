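import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from orthosite.synthetic import make_toy_domain, plant_ligand

TOY_SEQ = "ARNDCEQGHILKMFPSTWYVARNDC"


@pytest.fixture
def toy_domain():
    return make_toy_domain(TOY_SEQ, "helix", seed=1)


@pytest.fixture
def toy_complex(toy_domain):
    """Toy receptor with a pseudo-ligand planted on residues 5, 9, 12."""
    return plant_ligand(toy_domain, (5, 9, 12), distance=3.5, seed=11)


@pytest.fixture
def reference_dir():
    """Directory holding the public reference deposits, if fetched."""
    return Path(__file__).resolve().parent.parent / "data" / "reference"
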