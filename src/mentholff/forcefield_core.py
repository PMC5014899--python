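"""Single-molecule OPLS-AA intramolecular energy model.

Implements the classical intramolecular potential used throughout the
package: harmonic bond stretching and angle bending, the 4-term OPLS
Fourier torsion

    E(phi) = 1/2 [ V1 (1 + cos phi) + V2 (1 - cos 2 phi)
                 + V3 (1 + cos 3 phi) + V4 (1 - cos 4 phi) ],

and Lennard-Jones + Coulomb nonbonded interactions with geometric-mean
combining for both sigma and epsilon, exclusion of 1-2 and 1-3 pairs, and
0.5 scaling of 1-4 pairs.  Alongside the energy it provides conformation
manipulation: torsion measurement (IUPAC sign convention), rigid rotation
about a bond, and a steepest-descent minimizer with an adaptive step.

All quantities are in the package unit system (nm, kJ/mol, e, u, degrees
for angles at the API surface).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .units import KE_COULOMB

__all__ = [
    "ForceFieldError",
    "DegenerateGeometryError",
    "TopologyError",
    "SingularityError",
    "MinimizationError",
    "AtomType",
    "Atom",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "MolecularTopology",
    "Conformation",
    "EnergyBreakdown",
    "MinimizationResult",
    "fourier_energy",
    "fourier_energy_derivative",
    "opls_dihedral_energy",
    "nonbonded_pair_energy",
    "measure_dihedral",
    "intramolecular_energy",
    "forces",
    "finite_difference_forces",
    "rotate_dihedral",
    "moving_side",
    "steepest_descent_minimize",
    "enumerate_angles",
    "enumerate_dihedrals",
    "bonded_distances",
]


class ForceFieldError(Exception):
    """Base class for force-field evaluation errors."""


class DegenerateGeometryError(ForceFieldError):
    """Raised when a torsion is undefined (collinear atoms)."""


class TopologyError(ForceFieldError):
    """Raised on inconsistent topology / conformation input."""


class SingularityError(ForceFieldError):
    """Raised when interacting atoms coincide (r = 0)."""


class MinimizationError(ForceFieldError):
    """Raised when the minimizer encounters a non-finite energy."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomType:
    """A nonbonded atom type: LJ sigma [nm], epsilon [kJ/mol], default charge [e], mass [u]."""

    name: str
    sigma: float
    epsilon: float
    charge: float = 0.0
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"atom type {self.name}: sigma must be >= 0")
        if self.epsilon < 0:
            raise ValueError(f"atom type {self.name}: epsilon must be >= 0")


@dataclass(frozen=True)
class Atom:
    """One atom in a molecule: a type reference plus its per-atom charge [e]."""

    name: str
    type: AtomType
    charge: float


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond i-j: E = 1/2 k_r (r - r_eq)^2, r_eq [nm], k_r [kJ/mol/nm^2]."""

    i: int
    j: int
    r_eq: float
    k_r: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond indices must differ")
        if self.r_eq <= 0 or self.k_r <= 0:
            raise ValueError("bond r_eq and k_r must be positive")


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle i-j-k: E = 1/2 k_theta (theta - theta_eq)^2.

    theta_eq in degrees, k_theta in kJ/mol/rad^2 (the quadratic acts on
    radians, matching the GROMACS convention).
    """

    i: int
    j: int
    k: int
    theta_eq: float
    k_theta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_eq < 180.0):
            raise ValueError("theta_eq must lie in (0, 180) degrees")
        if self.k_theta <= 0:
            raise ValueError("k_theta must be positive")


@dataclass(frozen=True)
class DihedralTerm:
    """OPLS 4-term Fourier torsion on the chain i-j-k-l (j-k the central bond)."""

    i: int
    j: int
    k: int
    l: int
    v1: float = 0.0
    v2: float = 0.0
    v3: float = 0.0
    v4: float = 0.0
    type_key: str | None = None

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise ValueError("dihedral indices must be distinct")

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.v1, self.v2, self.v3, self.v4)


@dataclass
class Conformation:
    """Cartesian coordinates, shape (N, 3), in nm."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy())


@dataclass(frozen=True)
class EnergyBreakdown:
    """Intramolecular energy decomposition [kJ/mol]; total is the exact sum."""

    e_bond: float
    e_angle: float
    e_dihedral: float
    e_lj_intra: float
    e_coulomb_intra: float

    @property
    def total(self) -> float:
        return (
            self.e_bond
            + self.e_angle
            + self.e_dihedral
            + self.e_lj_intra
            + self.e_coulomb_intra
        )


# ---------------------------------------------------------------------------
# Connectivity helpers
# ---------------------------------------------------------------------------


def _adjacency(n_atoms: int, bonds: Iterable[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def bonded_distances(
    n_atoms: int, bonds: Iterable[tuple[int, int]], cutoff: int = 3
) -> dict[frozenset[int], int]:
    """Shortest bond-graph distance for every pair within ``cutoff`` bonds."""
    adj = _adjacency(n_atoms, bonds)
    dist: dict[frozenset[int], int] = {}
    for start in range(n_atoms):
        seen = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if seen[u] >= cutoff:
                continue
            for v in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    queue.append(v)
        for u, d in seen.items():
            if u != start:
                key = frozenset((start, u))
                if key not in dist or d < dist[key]:
                    dist[key] = d
    return dist


def enumerate_angles(n_atoms: int, bonds: Iterable[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All i-j-k bonded triples, each once (i < k)."""
    adj = _adjacency(n_atoms, bonds)
    out = []
    for j in range(n_atoms):
        nbrs = sorted(adj[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append((nbrs[a], j, nbrs[b]))
    return out


def enumerate_dihedrals(
    n_atoms: int, bonds: Iterable[tuple[int, int]]
) -> list[tuple[int, int, int, int]]:
    """All proper i-j-k-l bonded quadruples, each once (oriented j < k)."""
    bond_list = [tuple(sorted(b)) for b in bonds]
    adj = _adjacency(n_atoms, bond_list)
    out = []
    for j, k in sorted(set(bond_list)):
        for i in sorted(adj[j] - {k}):
            for l in sorted(adj[k] - {j}):
                if i != l:  # 3-membered rings would fold back
                    out.append((i, j, k, l))
    return out


class MolecularTopology:
    """Atoms, bonded terms and nonbonded bookkeeping for one molecule.

    1-2 and 1-3 pairs (by shortest bond-graph path) are excluded from the
    nonbonded sum; 1-4 pairs are kept at half strength; everything further
    apart interacts fully.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Sequence[BondTerm],
        angles: Sequence[AngleTerm] = (),
        dihedrals: Sequence[DihedralTerm] = (),
        exclusions: set[frozenset[int]] | None = None,
        pairs14: set[frozenset[int]] | None = None,
    ) -> None:
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.angles = list(angles)
        self.dihedrals = list(dihedrals)
        bond_pairs = [(b.i, b.j) for b in self.bonds]
        if exclusions is None or pairs14 is None:
            dist = bonded_distances(self.n_atoms, bond_pairs, cutoff=3)
            if exclusions is None:
                exclusions = {p for p, d in dist.items() if d <= 2}
            if pairs14 is None:
                pairs14 = {p for p, d in dist.items() if d == 3}
        if exclusions & pairs14:
            raise TopologyError("exclusions and 1-4 pairs must be disjoint")
        self.exclusions = exclusions
        self.pairs14 = pairs14
        self._cache: dict | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    @property
    def bond_pairs(self) -> list[tuple[int, int]]:
        return [(b.i, b.j) for b in self.bonds]

    def validate(self, charge_tol: float = 1e-6) -> None:
        n = self.n_atoms
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise TopologyError("bond index out of range")
        if abs(self.total_charge) > charge_tol:
            raise TopologyError(
                f"molecule not neutral: total charge {self.total_charge:.6g} e"
            )
        if self.exclusions & self.pairs14:
            raise TopologyError("exclusions and 1-4 pairs overlap")

    def with_charges(self, charges: Sequence[float]) -> "MolecularTopology":
        """Copy of this topology with per-atom charges replaced."""
        if len(charges) != self.n_atoms:
            raise TopologyError("charge list length mismatch")
        atoms = [
            Atom(a.name, a.type, float(q)) for a, q in zip(self.atoms, charges)
        ]
        return MolecularTopology(
            atoms, self.bonds, self.angles, self.dihedrals,
            exclusions=set(self.exclusions), pairs14=set(self.pairs14),
        )

    # -- vectorized term tables -------------------------------------------

    def _arrays(self) -> dict:
        if self._cache is not None:
            return self._cache
        c: dict = {}
        c["bond_idx"] = np.array([(b.i, b.j) for b in self.bonds], dtype=int).reshape(-1, 2)
        c["bond_req"] = np.array([b.r_eq for b in self.bonds], dtype=float)
        c["bond_k"] = np.array([b.k_r for b in self.bonds], dtype=float)
        c["ang_idx"] = np.array([(a.i, a.j, a.k) for a in self.angles], dtype=int).reshape(-1, 3)
        c["ang_eq"] = np.radians([a.theta_eq for a in self.angles])
        c["ang_k"] = np.array([a.k_theta for a in self.angles], dtype=float)
        c["dih_idx"] = np.array(
            [(d.i, d.j, d.k, d.l) for d in self.dihedrals], dtype=int
        ).reshape(-1, 4)
        c["dih_v"] = np.array(
            [d.coefficients for d in self.dihedrals], dtype=float
        ).reshape(-1, 4)
        pairs = []
        for pair in sorted(self.pairs14, key=sorted):
            i, j = sorted(pair)
            pairs.append((i, j, 0.5))
        n = self.n_atoms
        skip = self.exclusions | self.pairs14
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((i, j)) not in skip:
                    pairs.append((i, j, 1.0))
        c["pair_idx"] = np.array([(p[0], p[1]) for p in pairs], dtype=int).reshape(-1, 2)
        scale = np.array([p[2] for p in pairs], dtype=float)
        sig = np.array([a.type.sigma for a in self.atoms])
        eps = np.array([a.type.epsilon for a in self.atoms])
        q = np.array([a.charge for a in self.atoms])
        ii, jj = c["pair_idx"][:, 0], c["pair_idx"][:, 1]
        c["pair_sigma"] = np.sqrt(sig[ii] * sig[jj])
        c["pair_eps"] = scale * np.sqrt(eps[ii] * eps[jj])
        c["pair_qq"] = scale * KE_COULOMB * q[ii] * q[jj]
        self._cache = c
        return c


# ---------------------------------------------------------------------------
# Elementary energies
# ---------------------------------------------------------------------------


def fourier_energy(v: Sequence[float], phi_deg) -> np.ndarray | float:
    """OPLS 4-term Fourier torsion energy at phi (degrees)."""
    v1, v2, v3, v4 = v
    phi = np.radians(phi_deg)
    e = 0.5 * (
        v1 * (1.0 + np.cos(phi))
        + v2 * (1.0 - np.cos(2.0 * phi))
        + v3 * (1.0 + np.cos(3.0 * phi))
        + v4 * (1.0 - np.cos(4.0 * phi))
    )
    return e if np.ndim(phi_deg) else float(e)


def fourier_energy_derivative(v: Sequence[float], phi_rad) -> np.ndarray | float:
    """dE/dphi in kJ/mol/rad at phi (radians)."""
    v1, v2, v3, v4 = v
    return 0.5 * (
        -v1 * np.sin(phi_rad)
        + 2.0 * v2 * np.sin(2.0 * phi_rad)
        - 3.0 * v3 * np.sin(3.0 * phi_rad)
        + 4.0 * v4 * np.sin(4.0 * phi_rad)
    )


def opls_dihedral_energy(term: DihedralTerm, phi_deg) -> float:
    """Energy of one OPLS torsion term at torsion angle phi [degrees]."""
    if not np.all(np.isfinite(phi_deg)):
        raise ValueError("phi must be finite")
    return fourier_energy(term.coefficients, phi_deg)


def nonbonded_pair_energy(
    a: AtomType,
    b: AtomType,
    r: float,
    q_a: float | None = None,
    q_b: float | None = None,
    scale14: bool = False,
) -> tuple[float, float]:
    """LJ and Coulomb energy [kJ/mol] of one atom pair at separation r [nm].

    Geometric-mean combining for both sigma and epsilon; both contributions
    are halved when ``scale14`` marks the pair as a 1-4 interaction.
    """
    q_a = a.charge if q_a is None else q_a
    q_b = b.charge if q_b is None else q_b
    interacting = (a.epsilon > 0 and b.epsilon > 0) or (q_a * q_b != 0)
    if r <= 0:
        if interacting:
            raise SingularityError("r = 0 for an interacting pair")
        return 0.0, 0.0
    sigma = math.sqrt(a.sigma * b.sigma)
    eps = math.sqrt(a.epsilon * b.epsilon)
    sr6 = (sigma / r) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    e_coul = KE_COULOMB * q_a * q_b / r
    if scale14:
        e_lj *= 0.5
        e_coul *= 0.5
    return e_lj, e_coul


# ---------------------------------------------------------------------------
# Torsion geometry
# ---------------------------------------------------------------------------


def _dihedral_angles_rad(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized torsion angles [rad] for index rows (i, j, k, l)."""
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    if np.any(norm1 < 1e-12) or np.any(norm2 < 1e-12):
        raise DegenerateGeometryError("torsion undefined: collinear atoms")
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    xcomp = np.einsum("ij,ij->i", n1, n2)
    ycomp = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.arctan2(ycomp, xcomp)


def measure_dihedral(conf: Conformation, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle of the i-j-k-l chain, degrees in (-180, 180], IUPAC sign."""
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral indices must be distinct")
    idx = np.array([[i, j, k, l]])
    phi = math.degrees(_dihedral_angles_rad(conf.coordinates, idx)[0])
    if phi <= -180.0:
        phi += 360.0
    return phi


def moving_side(top: MolecularTopology, j: int, k: int) -> set[int]:
    """Connected component containing k after deleting the j-k bond."""
    adj = _adjacency(top.n_atoms, top.bond_pairs)
    if k not in adj[j]:
        raise TopologyError(f"no bond between atoms {j} and {k}")
    adj[j].discard(k)
    adj[k].discard(j)
    seen = {k}
    queue = deque([k])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    if j in seen:
        raise TopologyError("bond j-k lies on a ring: sides are not separable")
    return seen


def rotate_dihedral(
    conf: Conformation,
    j: int,
    k: int,
    moving_set: Iterable[int],
    delta_deg: float,
) -> Conformation:
    """Rigidly rotate ``moving_set`` about the j->k axis by delta [degrees].

    The sign convention is chosen so that any torsion i-j-k-l whose l lies in
    the moving set increases by delta (mod 360).  Internal geometry of the
    moving set is preserved exactly (rigid rotation).
    """
    moving = sorted(set(int(m) for m in moving_set))
    if j in moving:
        raise TopologyError("moving set must not contain the fixed-side atom j")
    x = conf.coordinates.copy()
    axis = x[k] - x[j]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateGeometryError("zero-length rotation axis")
    u = axis / norm
    theta = math.radians(delta_deg)
    c, s = math.cos(theta), math.sin(theta)
    rel = x[moving] - x[j]
    # Rodrigues rotation, right-handed about u (j -> k).
    rot = (
        rel * c
        + np.cross(u, rel) * s
        + np.outer(rel @ u, u) * (1.0 - c)
    )
    x[moving] = rot + x[j]
    return Conformation(x)


# ---------------------------------------------------------------------------
# Energy and forces
# ---------------------------------------------------------------------------


def intramolecular_energy(top: MolecularTopology, conf: Conformation) -> EnergyBreakdown:
    """Full intramolecular energy decomposition for one conformation."""
    if conf.n_atoms != top.n_atoms:
        raise TopologyError(
            f"conformation has {conf.n_atoms} atoms, topology {top.n_atoms}"
        )
    x = conf.coordinates
    c = top._arrays()

    e_bond = 0.0
    if len(c["bond_idx"]):
        d = x[c["bond_idx"][:, 0]] - x[c["bond_idx"][:, 1]]
        r = np.linalg.norm(d, axis=1)
        e_bond = float(np.sum(0.5 * c["bond_k"] * (r - c["bond_req"]) ** 2))

    e_angle = 0.0
    if len(c["ang_idx"]):
        u = x[c["ang_idx"][:, 0]] - x[c["ang_idx"][:, 1]]
        v = x[c["ang_idx"][:, 2]] - x[c["ang_idx"][:, 1]]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        e_angle = float(np.sum(0.5 * c["ang_k"] * (theta - c["ang_eq"]) ** 2))

    e_dih = 0.0
    if len(c["dih_idx"]):
        phi = _dihedral_angles_rad(x, c["dih_idx"])
        vv = c["dih_v"]
        e_dih = float(
            np.sum(
                0.5
                * (
                    vv[:, 0] * (1 + np.cos(phi))
                    + vv[:, 1] * (1 - np.cos(2 * phi))
                    + vv[:, 2] * (1 + np.cos(3 * phi))
                    + vv[:, 3] * (1 - np.cos(4 * phi))
                )
            )
        )

    e_lj = e_coul = 0.0
    if len(c["pair_idx"]):
        d = x[c["pair_idx"][:, 0]] - x[c["pair_idx"][:, 1]]
        r = np.linalg.norm(d, axis=1)
        active = (c["pair_eps"] > 0) | (c["pair_qq"] != 0)
        if np.any(r[active] <= 0):
            raise SingularityError("coincident atoms in nonbonded pair")
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = np.where(r > 0, (c["pair_sigma"] / np.where(r > 0, r, 1.0)) ** 6, 0.0)
            e_lj = float(np.sum(4.0 * c["pair_eps"] * (sr6 * sr6 - sr6)))
            e_coul = float(np.sum(np.where(r > 0, c["pair_qq"] / np.where(r > 0, r, 1.0), 0.0)))

    return EnergyBreakdown(e_bond, e_angle, e_dih, e_lj, e_coul)


def forces(top: MolecularTopology, conf: Conformation) -> np.ndarray:
    """Analytic forces -dE/dx, shape (N, 3), kJ/mol/nm."""
    if conf.n_atoms != top.n_atoms:
        raise TopologyError("conformation/topology atom count mismatch")
    x = conf.coordinates
    c = top._arrays()
    f = np.zeros_like(x)

    if len(c["bond_idx"]):
        ii, jj = c["bond_idx"][:, 0], c["bond_idx"][:, 1]
        d = x[ii] - x[jj]
        r = np.linalg.norm(d, axis=1)
        fac = -c["bond_k"] * (r - c["bond_req"]) / r
        fij = fac[:, None] * d
        np.add.at(f, ii, fij)
        np.add.at(f, jj, -fij)

    if len(c["ang_idx"]):
        ii, jj, kk = c["ang_idx"][:, 0], c["ang_idx"][:, 1], c["ang_idx"][:, 2]
        u = x[ii] - x[jj]
        v = x[kk] - x[jj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cosang)
        sin = np.sqrt(np.clip(1.0 - cosang**2, 1e-16, None))
        dedtheta = c["ang_k"] * (theta - c["ang_eq"])
        fi = -dedtheta[:, None] * (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
        fk = -dedtheta[:, None] * (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
        np.add.at(f, ii, fi)
        np.add.at(f, kk, fk)
        np.add.at(f, jj, -(fi + fk))

    if len(c["dih_idx"]):
        idx = c["dih_idx"]
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        m = np.cross(b1, b2)
        n = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        phi = _dihedral_angles_rad(x, idx)
        dedphi = fourier_energy_derivative(c["dih_v"].T, phi)
        m2 = np.einsum("ij,ij->i", m, m)
        n2 = np.einsum("ij,ij->i", n, n)
        fi = dedphi[:, None] * (nb2 / m2)[:, None] * m
        fl = -dedphi[:, None] * (nb2 / n2)[:, None] * n
        t = np.einsum("ij,ij->i", b1, b2) / nb2**2
        s = np.einsum("ij,ij->i", b3, b2) / nb2**2
        fj = -(1.0 + t)[:, None] * fi + s[:, None] * fl
        fk = -(fi + fj + fl)
        np.add.at(f, idx[:, 0], fi)
        np.add.at(f, idx[:, 1], fj)
        np.add.at(f, idx[:, 2], fk)
        np.add.at(f, idx[:, 3], fl)

    if len(c["pair_idx"]):
        ii, jj = c["pair_idx"][:, 0], c["pair_idx"][:, 1]
        d = x[ii] - x[jj]
        r2 = np.einsum("ij,ij->i", d, d)
        r = np.sqrt(r2)
        sr6 = (c["pair_sigma"] ** 2 / r2) ** 3
        # -dE/dr for LJ + Coulomb, then radial direction
        dedr = (-24.0 * c["pair_eps"] * (2.0 * sr6 * sr6 - sr6) / r
                - c["pair_qq"] / r2)
        fij = (-dedr / r)[:, None] * d
        np.add.at(f, ii, fij)
        np.add.at(f, jj, -fij)

    return f


def finite_difference_forces(
    top: MolecularTopology, conf: Conformation, h: float = 1e-6
) -> np.ndarray:
    """Central-difference forces; the reference for force-consistency checks."""
    x0 = conf.coordinates
    f = np.zeros_like(x0)
    for a in range(x0.shape[0]):
        for d in range(3):
            xp = x0.copy()
            xp[a, d] += h
            xm = x0.copy()
            xm[a, d] -= h
            ep = intramolecular_energy(top, Conformation(xp)).total
            em = intramolecular_energy(top, Conformation(xm)).total
            f[a, d] = -(ep - em) / (2.0 * h)
    return f


@dataclass
class MinimizationResult:
    conformation: Conformation
    converged: bool
    n_steps: int
    energy: float
    max_force: float


def steepest_descent_minimize(
    top: MolecularTopology,
    conf: Conformation,
    force_tol: float = 200.0,
    max_steps: int = 2000,
    initial_step: float = 0.01,
) -> MinimizationResult:
    """Steepest-descent relaxation until every atomic force norm <= force_tol.

    Adaptive displacement: the largest atomic move per step starts at
    ``initial_step`` nm, grows 1.2x after an accepted (energy-decreasing)
    step and shrinks 0.5x after a rejected one.  Energy never increases
    across accepted steps.
    """
    x = conf.coordinates.copy()
    e = intramolecular_energy(top, Conformation(x)).total
    if not math.isfinite(e):
        raise MinimizationError("non-finite energy at start")
    step = initial_step
    n = 0
    while n < max_steps:
        f = forces(top, Conformation(x))
        fmax = float(np.max(np.linalg.norm(f, axis=1)))
        if fmax <= force_tol:
            return MinimizationResult(Conformation(x), True, n, e, fmax)
        trial = x + f * (step / fmax)
        e_trial = intramolecular_energy(top, Conformation(trial)).total
        if math.isnan(e_trial):
            raise MinimizationError(f"NaN energy at step {n}, step size {step:.3g} nm")
        n += 1
        if e_trial < e:
            x, e = trial, e_trial
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-10:
                break
    f = forces(top, Conformation(x))
    fmax = float(np.max(np.linalg.norm(f, axis=1)))
    return MinimizationResult(Conformation(x), fmax <= force_tol, n, e, fmax)
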