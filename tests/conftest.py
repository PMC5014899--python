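import numpy as np
import pytest
from hypothesis import settings

from mentholff.forcefield_core import (
    AngleTerm,
    Atom,
    AtomType,
    BondTerm,
    Conformation,
    DihedralTerm,
    MolecularTopology,
)
from mentholff.topology_io import build_menthol

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def menthol():
    """(topology, parameters, conformation) of the published menthol set."""
    return build_menthol("published")


@pytest.fixture(scope="session")
def menthol_original():
    return build_menthol("original")


@pytest.fixture
def ct_type():
    return AtomType("CT", 0.35, 0.276144, mass=12.011)


@pytest.fixture
def toy_chain5(ct_type):
    """5-atom linear chain with hand-set parameters and a bent conformation.

    Charges sum to zero; every term class (bond, angle, torsion, 1-4 and
    1-5 nonbonded pairs) is exercised.
    """
    charges = [0.10, -0.20, 0.20, -0.20, 0.10]
    atoms = [Atom(f"A{i}", ct_type, q) for i, q in enumerate(charges)]
    bonds = [BondTerm(i, i + 1, 0.153, 1000.0) for i in range(4)]
    angles = [AngleTerm(i, i + 1, i + 2, 112.7, 400.0) for i in range(3)]
    dihedrals = [
        DihedralTerm(0, 1, 2, 3, 5.44, -0.21, 0.84, 0.30),
        DihedralTerm(1, 2, 3, 4, 7.448, -1.430, 7.261, 0.0),
    ]
    top = MolecularTopology(atoms, bonds, angles, dihedrals)
    from mentholff.topology_io import _nerf_place

    x = np.zeros((5, 3))
    x[0] = (0.16, 0.0, 0.0)
    x[1] = (0.0, 0.0, 0.0)
    th = np.radians(115.0)
    x[2] = x[1] + 0.15 * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0.0])
    x[3] = _nerf_place(x[0], x[1], x[2], 0.155, 109.0, 55.0)
    x[4] = _nerf_place(x[1], x[2], x[3], 0.150, 117.0, -160.0)
    return top, Conformation(x)


@pytest.fixture
def butane_like(ct_type):
    """Uncharged, epsilon-free 4-carbon chain in a gauche conformation."""
    null = AtomType("CX", 0.35, 0.0, mass=12.011)
    atoms = [Atom(f"C{i}", null, 0.0) for i in range(4)]
    bonds = [BondTerm(i, i + 1, 0.153, 224262.4) for i in range(3)]
    angles = [AngleTerm(i, i + 1, i + 2, 112.7, 488.273) for i in range(2)]
    dihedrals = [DihedralTerm(0, 1, 2, 3, -3.3472, -0.2092, 0.8368, 0.0)]
    top = MolecularTopology(atoms, bonds, angles, dihedrals)
    # exact internal coordinates: all bonds 0.153 nm, angles 112.7 deg, torsion 60 deg
    from mentholff.topology_io import _nerf_place

    x = np.zeros((4, 3))
    x[0] = (0.153, 0.0, 0.0)
    x[1] = (0.0, 0.0, 0.0)
    th = np.radians(180.0 - 112.7)
    x[2] = x[1] + 0.153 * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0.0])
    x[3] = _nerf_place(x[0], x[1], x[2], 0.153, 112.7, 60.0)
    return top, Conformation(x)
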