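"""Unit and property tests for the intramolecular energy core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mentholff.forcefield_core import (
    AtomType,
    Atom,
    BondTerm,
    AngleTerm,
    Conformation,
    DegenerateGeometryError,
    DihedralTerm,
    MolecularTopology,
    SingularityError,
    TopologyError,
    bonded_distances,
    finite_difference_forces,
    forces,
    intramolecular_energy,
    measure_dihedral,
    nonbonded_pair_energy,
    opls_dihedral_energy,
    rotate_dihedral,
    steepest_descent_minimize,
)
from mentholff.units import KE_COULOMB

# ---------------------------------------------------------------------------
# torsion measurement
# ---------------------------------------------------------------------------


def test_measure_dihedral_planar_cis_and_trans():
    cis = Conformation([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]])
    assert measure_dihedral(cis, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)
    trans = Conformation([[1, 1, 0], [0, 1, 0], [0, 0, 0], [-1, 0, 0]])
    assert measure_dihedral(trans, 0, 1, 2, 3) == pytest.approx(180.0, abs=1e-12)


def test_measure_dihedral_explicit_rotation_construction():
    """l placed by an explicit rotation matrix at a 60-degree twist about j-k."""
    phi = math.radians(60.0)
    rot_z = np.array(
        [[math.cos(phi), -math.sin(phi), 0], [math.sin(phi), math.cos(phi), 0], [0, 0, 1]]
    )
    l = rot_z @ np.array([1.0, 0.0, 0.0]) + np.array([0.0, 0.0, 2.0])
    conf = Conformation([[1, 0, -1], [0, 0, 0], [0, 0, 1], l])
    assert measure_dihedral(conf, 0, 1, 2, 3) == pytest.approx(60.0, abs=1e-9)


def test_measure_dihedral_collinear_raises():
    conf = Conformation([[0, 0, -1], [0, 0, 0], [0, 0, 1], [1, 0, 2]])
    with pytest.raises(DegenerateGeometryError):
        measure_dihedral(conf, 0, 1, 2, 3)


# ---------------------------------------------------------------------------
# OPLS torsion energy
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "v, phi, expected",
    [
        ((0, 0, 0, 0), 123.4, 0.0),  # the published HC-CT-O-HO row is all zero
        ((0, 0, 0, 0), 37.2, 0.0),
        # hand evaluation of the Fourier form with the hydroxyl coefficients
        ((7.448, -1.430, 7.261, 0.0), 0.0, 14.709),
    ],
)
def test_opls_dihedral_energy_values(v, phi, expected):
    term = DihedralTerm(0, 1, 2, 3, *v)
    assert opls_dihedral_energy(term, phi) == pytest.approx(expected, abs=1e-9)


@given(
    phi=st.floats(-720, 720),
    v=st.tuples(*[st.floats(-20, 20) for _ in range(4)]),
)
def test_opls_dihedral_energy_periodic(phi, v):
    term = DihedralTerm(0, 1, 2, 3, *v)
    assert opls_dihedral_energy(term, phi) == pytest.approx(
        opls_dihedral_energy(term, phi + 360.0), abs=1e-10
    )


# ---------------------------------------------------------------------------
# nonbonded pairs
# ---------------------------------------------------------------------------


def test_lj_zero_crossing_and_minimum():
    a = AtomType("CT", 0.35, 0.5)
    e_lj, _ = nonbonded_pair_energy(a, a, 0.35)
    assert e_lj == pytest.approx(0.0, abs=1e-12)
    e_lj, _ = nonbonded_pair_energy(a, a, 2 ** (1 / 6) * 0.35)
    assert e_lj == pytest.approx(-0.5, abs=1e-12)


def test_coulomb_conversion_constant():
    a = AtomType("ion", 0.0, 0.0, charge=1.0)
    b = AtomType("ion2", 0.0, 0.0, charge=-1.0)
    _, e_c = nonbonded_pair_energy(a, b, 1.0)
    assert e_c == pytest.approx(-KE_COULOMB, abs=1e-9)
    _, e_c14 = nonbonded_pair_energy(a, b, 1.0, scale14=True)
    assert e_c14 == pytest.approx(-0.5 * KE_COULOMB, abs=1e-9)


def test_singularity_raises():
    a = AtomType("ion", 0.0, 0.0, charge=1.0)
    with pytest.raises(SingularityError):
        nonbonded_pair_energy(a, a, 0.0)


# ---------------------------------------------------------------------------
# total intramolecular energy: independent brute-force oracle
# ---------------------------------------------------------------------------


def _brute_force_energy(top, conf):
    """Explicit per-term loops with shortest-path pair classification."""
    x = conf.coordinates
    n = top.n_atoms
    # Floyd-Warshall bond-graph distances (independent of the BFS in the package)
    big = 10**6
    dist = [[0 if i == j else big for j in range(n)] for i in range(n)]
    for b in top.bonds:
        dist[b.i][b.j] = dist[b.j][b.i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]

    e_bond = sum(
        0.5 * b.k_r * (math.dist(x[b.i], x[b.j]) - b.r_eq) ** 2 for b in top.bonds
    )
    e_angle = 0.0
    for a in top.angles:
        u = x[a.i] - x[a.j]
        v = x[a.k] - x[a.j]
        th = math.acos(
            float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
        )
        e_angle += 0.5 * a.k_theta * (th - math.radians(a.theta_eq)) ** 2
    e_dih = 0.0
    for d in top.dihedrals:
        phi = math.radians(measure_dihedral(conf, d.i, d.j, d.k, d.l))
        e_dih += 0.5 * (
            d.v1 * (1 + math.cos(phi))
            + d.v2 * (1 - math.cos(2 * phi))
            + d.v3 * (1 + math.cos(3 * phi))
            + d.v4 * (1 - math.cos(4 * phi))
        )
    e_lj = e_c = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i][j] <= 2:
                continue
            scale = 0.5 if dist[i][j] == 3 else 1.0
            r = math.dist(x[i], x[j])
            ai, aj = top.atoms[i], top.atoms[j]
            sig = math.sqrt(ai.type.sigma * aj.type.sigma)
            eps = math.sqrt(ai.type.epsilon * aj.type.epsilon)
            sr6 = (sig / r) ** 6
            e_lj += scale * 4 * eps * (sr6**2 - sr6)
            e_c += scale * KE_COULOMB * ai.charge * aj.charge / r
    return e_bond + e_angle + e_dih + e_lj + e_c


def test_energy_matches_brute_force_on_toy_chain(toy_chain5):
    top, conf = toy_chain5
    eb = intramolecular_energy(top, conf)
    assert eb.total == pytest.approx(_brute_force_energy(top, conf), abs=1e-9)


def test_energy_matches_brute_force_on_six_ring(ct_type):
    """Cyclohexane-like 6-ring: ring closure makes some 1-4 paths ambiguous."""
    charges = [0.1, -0.1, 0.1, -0.1, 0.1, -0.1]
    atoms = [Atom(f"C{i}", ct_type, q) for i, q in enumerate(charges)]
    bonds = [BondTerm(i, (i + 1) % 6, 0.153, 1000.0) for i in range(6)]
    angles = [AngleTerm(i, (i + 1) % 6, (i + 2) % 6, 112.7, 400.0) for i in range(6)]
    dihedrals = [
        DihedralTerm(i, (i + 1) % 6, (i + 2) % 6, (i + 3) % 6, 1.0, -0.5, 0.3, 0.0)
        for i in range(6)
    ]
    top = MolecularTopology(atoms, bonds, angles, dihedrals)
    rng = np.random.default_rng(7)
    # puckered ring
    ang = np.radians(np.arange(6) * 60.0)
    x = np.column_stack(
        [0.147 * np.cos(ang), 0.147 * np.sin(ang), 0.02 * (-1) ** np.arange(6)]
    )
    x += rng.normal(0, 0.005, x.shape)
    conf = Conformation(x)
    eb = intramolecular_energy(top, conf)
    assert eb.total == pytest.approx(_brute_force_energy(top, conf), abs=1e-9)


def test_breakdown_total_is_component_sum(toy_chain5):
    top, conf = toy_chain5
    eb = intramolecular_energy(top, conf)
    s = eb.e_bond + eb.e_angle + eb.e_dihedral + eb.e_lj_intra + eb.e_coulomb_intra
    assert eb.total == pytest.approx(s, rel=1e-12)


def test_rigid_motion_invariance(toy_chain5):
    top, conf = toy_chain5
    ref = intramolecular_energy(top, conf)
    rng = np.random.default_rng(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = 1.234
    k_mat = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + math.sin(theta) * k_mat + (1 - math.cos(theta)) * k_mat @ k_mat
    moved = Conformation(conf.coordinates @ rot.T + np.array([1.0, -2.0, 0.5]))
    eb = intramolecular_energy(top, moved)
    for name in ("e_bond", "e_angle", "e_dihedral", "e_lj_intra", "e_coulomb_intra"):
        assert getattr(eb, name) == pytest.approx(getattr(ref, name), abs=1e-9)


def test_bond_at_equilibrium_is_zero(ct_type):
    top = MolecularTopology(
        [Atom("a", ct_type, 0.0), Atom("b", ct_type, 0.0)],
        [BondTerm(0, 1, 0.153, 224262.4)],
    )
    conf = Conformation([[0, 0, 0], [0.153, 0, 0]])
    assert intramolecular_energy(top, conf).e_bond == pytest.approx(0.0, abs=1e-12)


def test_atom_count_mismatch_raises(toy_chain5):
    top, conf = toy_chain5
    with pytest.raises(TopologyError):
        intramolecular_energy(top, Conformation(conf.coordinates[:-1]))


def test_analytic_forces_match_central_differences(toy_chain5):
    top, conf = toy_chain5
    fa = forces(top, conf)
    fd = finite_difference_forces(top, conf)
    scale = np.abs(fd).max()
    assert np.abs(fa - fd).max() / scale < 1e-6


# ---------------------------------------------------------------------------
# rigid torsion rotation
# ---------------------------------------------------------------------------


def test_rotate_identity_and_full_turn(butane_like):
    top, conf = butane_like
    for delta in (0.0, 360.0):
        out = rotate_dihedral(conf, 1, 2, {2, 3}, delta)
        assert np.abs(out.coordinates - conf.coordinates).max() < 1e-9


def test_rotation_composition(butane_like):
    _, conf = butane_like
    a = rotate_dihedral(rotate_dihedral(conf, 1, 2, {2, 3}, 70.0), 1, 2, {2, 3}, 50.0)
    b = rotate_dihedral(conf, 1, 2, {2, 3}, 120.0)
    assert np.abs(a.coordinates - b.coordinates).max() < 1e-9


def test_rotation_increments_dihedral_and_preserves_geometry(menthol):
    top, _params, conf = menthol
    from mentholff.forcefield_core import moving_side
    from mentholff.topology_io import _IDX

    j, k = _IDX["C1"], _IDX["O1"]
    i, l = _IDX["C2"], _IDX["HO1"]
    moving = moving_side(top, j, k)
    phi0 = measure_dihedral(conf, i, j, k, l)
    out = rotate_dihedral(conf, j, k, moving, 25.0)
    phi1 = measure_dihedral(out, i, j, k, l)
    assert (phi1 - phi0) % 360.0 == pytest.approx(25.0, abs=1e-9)
    fixed = sorted(set(range(top.n_atoms)) - moving)
    assert np.abs(out.coordinates[fixed] - conf.coordinates[fixed]).max() == 0.0
    # internal geometry of the moving set is preserved
    mv = sorted(moving)
    d0 = np.linalg.norm(
        conf.coordinates[mv][:, None] - conf.coordinates[mv][None], axis=-1
    )
    d1 = np.linalg.norm(out.coordinates[mv][:, None] - out.coordinates[mv][None], axis=-1)
    assert np.abs(d1 - d0).max() < 1e-9


def test_rotate_moving_set_containing_j_raises(butane_like):
    _, conf = butane_like
    with pytest.raises(TopologyError):
        rotate_dihedral(conf, 1, 2, {1, 2, 3}, 10.0)


# ---------------------------------------------------------------------------
# steepest descent
# ---------------------------------------------------------------------------


def test_minimize_at_minimum_returns_input(ct_type):
    top = MolecularTopology(
        [Atom("a", ct_type, 0.0), Atom("b", ct_type, 0.0)],
        [BondTerm(0, 1, 0.153, 224262.4)],
    )
    conf = Conformation([[0, 0, 0], [0.153, 0, 0]])
    res = steepest_descent_minimize(top, conf)
    assert res.converged and res.n_steps == 0
    assert np.array_equal(res.conformation.coordinates, conf.coordinates)


def test_minimize_stretched_bond(ct_type):
    top = MolecularTopology(
        [Atom("a", ct_type, 0.0), Atom("b", ct_type, 0.0)],
        [BondTerm(0, 1, 0.153, 224262.4)],
    )
    res = steepest_descent_minimize(
        top, Conformation([[0, 0, 0], [0.25, 0, 0]]), force_tol=1.0
    )
    r = np.linalg.norm(np.diff(res.conformation.coordinates, axis=0))
    assert res.converged
    assert abs(r - 0.153) < 1e-4


def test_minimize_bent_angle(ct_type):
    atoms = [Atom(f"a{i}", ct_type, 0.0) for i in range(3)]
    top = MolecularTopology(
        atoms,
        [BondTerm(0, 1, 0.153, 224262.4), BondTerm(1, 2, 0.153, 224262.4)],
        [AngleTerm(0, 1, 2, 110.0, 400.0)],
    )
    th = math.radians(130.0)  # 20 degrees past equilibrium
    conf = Conformation(
        [[0.153, 0, 0], [0, 0, 0], [0.153 * math.cos(th), 0.153 * math.sin(th), 0]]
    )
    res = steepest_descent_minimize(top, conf, force_tol=0.05, max_steps=20000)
    u = res.conformation.coordinates[0] - res.conformation.coordinates[1]
    v = res.conformation.coordinates[2] - res.conformation.coordinates[1]
    final = math.degrees(
        math.acos(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    )
    assert abs(final - 110.0) < 0.1


# ---------------------------------------------------------------------------
# connectivity bookkeeping
# ---------------------------------------------------------------------------


def test_bonded_distances_chain():
    dist = bonded_distances(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
    assert dist[frozenset((0, 3))] == 3
    assert dist[frozenset((0, 2))] == 2
    assert frozenset((0, 4)) not in {k for k, d in dist.items() if d <= 3} - set(dist)


def test_exclusion_pair_partition(toy_chain5):
    top, _ = toy_chain5
    assert top.exclusions == {
        frozenset(p) for p in [(0, 1), (1, 2), (2, 3), (3, 4), (0, 2), (1, 3), (2, 4)]
    }
    assert top.pairs14 == {frozenset((0, 3)), frozenset((1, 4))}
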