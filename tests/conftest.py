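import numpy as np
import pytest

from scaffoldforge import structio as sio
from scaffoldforge.fusion_sampler import build_ideal_helix


@pytest.fixture
def helix5():
    """Toy 5-residue poly-ALA ideal helix (5 atoms per residue)."""
    return build_ideal_helix(5)


@pytest.fixture
def helix12():
    return build_ideal_helix(12)


def random_rigid_transform(rng) -> sio.RigidTransform:
    """Uniform-ish random proper rotation + bounded translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return sio.RigidTransform(Q, rng.uniform(-10, 10, 3))


def single_atom_structure(name="C1", element="C", coord=(0.0, 0.0, 0.0),
                          resname="GLY", chain="A", seq=1):
    return sio.Structure(
        "s", [(chain, [sio.Residue(resname, seq, "",
                                   [sio.Atom(name, element, np.array(coord))])])])
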