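import numpy as np
import pytest

from cavscan.fixtures import make_concave_bundle, make_ideal_helix, make_toy_dimer
from cavscan.structio import Atom, Chain, Residue, Structure


def single_atom_structure(coords=(0.0, 0.0, 0.0), element="C", name="CA"):
    atom = Atom(serial=1, name=name, element=element, coords=np.array(coords, float))
    res = Residue(name="GLY", resnum=1, atoms=[atom])
    return Structure(chains=[Chain(id="A", residues=[res])])


def ca_structure(coords, chain_id="A", element="C"):
    """One CA-only residue per coordinate."""
    chain = Chain(id=chain_id)
    for i, c in enumerate(coords):
        atom = Atom(serial=i + 1, name="CA", element=element, coords=np.array(c, float))
        chain.residues.append(Residue(name="GLY", resnum=i + 1, atoms=[atom]))
    return Structure(chains=[chain])


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-30, 30, 3)


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def helix20_backbone():
    return make_ideal_helix(20, backbone=True)


@pytest.fixture(scope="session")
def bundle15():
    return make_concave_bundle(face_radius=15.0)


@pytest.fixture(scope="session")
def dimer():
    return make_toy_dimer(contact_gap=0.5, seed=1)


@pytest.fixture(scope="session")
def dimer_far():
    return make_toy_dimer(contact_gap=50.0, seed=1)
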