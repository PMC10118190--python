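import numpy as np
import pytest

from gefprobe.structures import Atom, Structure


def make_atom(serial, name, resnum, xyz, chain="A", element=None, resname="ALA"):
    if element is None:
        element = name[0]
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        chain_id=chain, residue_number=resnum, coords=np.asarray(xyz, float),
    )


@pytest.fixture
def toy_structure():
    """Three-residue CA-only chain on the x axis."""
    atoms = [make_atom(i + 1, "CA", i + 1, [3.8 * i, 0.0, 0.0]) for i in range(3)]
    return Structure(atoms=atoms, label="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
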