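import numpy as np
import pytest

from piface.interface_extract import extract_interface
from piface.structure_io import Atom, Residue, Structure
from piface.synthetic_fixtures import ToyComplexSpec, make_toy_complex


def carbon(x, y, z, name="C1"):
    return Atom(name=name, element="C", coord=(float(x), float(y), float(z)), vdw_radius=1.70)


def ala_residue(chain_id, seq_id, ca_xyz, aa_type="ALA", extra_atoms=()):
    """Minimal residue: a CA atom at ca_xyz plus optional extra atoms."""
    x, y, z = ca_xyz
    atoms = (Atom(name="CA", element="C", coord=(float(x), float(y), float(z)), vdw_radius=1.70),) + tuple(extra_atoms)
    return Residue(chain_id=chain_id, seq_id=seq_id, icode="", aa_type=aa_type, atoms=atoms)


def two_chain_structure(chain_residues: dict, pdb_id="TEST"):
    return Structure(pdb_id=pdb_id, models={0: chain_residues}, model_index=0, filtered=True)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(perturbation_sigma=0.05, seed=11))


@pytest.fixture(scope="session")
def toy_interface(toy_complex):
    iface = extract_interface(toy_complex, "A", "B")
    assert iface is not None
    return iface


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
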