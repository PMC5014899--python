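"""Menthol parameter set, parameter transforms, and GROMACS topology I/O.

Builds the menthol molecule (C10H20O, 31 atoms) with either the original
OPLS-AA parameters or the published, reoptimized set (refit hydroxyl and
isopropyl torsions, epsilon scaled to 118.75 %, charges depolarized to
85 % with NPA hydroxyl charges), applies the individual parameter
transformations, and reads/writes the GROMACS .itp dialect with
Ryckaert-Bellemans (funct 3) torsions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import reference_data as ref
from .forcefield_core import (
    Atom,
    AtomType,
    AngleTerm,
    BondTerm,
    Conformation,
    DihedralTerm,
    MolecularTopology,
    fourier_energy,
    measure_dihedral,
)

__all__ = [
    "ForceFieldParameters",
    "ParseError",
    "ParameterLookupError",
    "build_menthol",
    "scale_epsilon",
    "scale_charges",
    "set_hydroxyl_npa_charges",
    "fourier_to_rb",
    "rb_to_fourier",
    "write_topology",
    "read_topology",
    "MENTHOL_ATOM_NAMES",
    "MENTHOL_BONDS",
]


class ParseError(Exception):
    """Malformed topology file; message carries the line number."""


class ParameterLookupError(KeyError):
    """A type tuple required by the topology has no parameter entry."""


def _canon_bond(a: str, b: str) -> tuple[str, str]:
    return (a, b) if (a, b) <= (b, a) else (b, a)


def _canon_angle(t: tuple[str, str, str]) -> tuple[str, str, str]:
    return min(t, t[::-1])


def _canon_dihedral(t: tuple[str, str, str, str]) -> str:
    return "-".join(min(t, t[::-1]))


@dataclass
class ForceFieldParameters:
    """Typed parameter tables with per-entry provenance tags.

    ``atom_charges`` carries the per-atom charges of the embedded menthol
    molecule keyed by atom name (the same atom type appears with several
    different charges, so charges cannot live on the type alone).
    """

    atom_types: dict[str, AtomType]
    bond_types: dict[tuple[str, str], tuple[float, float]]
    angle_types: dict[tuple[str, str, str], tuple[float, float]]
    dihedral_types: dict[str, tuple[float, float, float, float]]
    atom_charges: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "ForceFieldParameters":
        return ForceFieldParameters(
            dict(self.atom_types),
            dict(self.bond_types),
            dict(self.angle_types),
            dict(self.dihedral_types),
            dict(self.atom_charges),
            dict(self.provenance),
        )

    def resolve_bond(self, a: str, b: str) -> tuple[float, float]:
        key = _canon_bond(a, b)
        if key not in self.bond_types:
            raise ParameterLookupError(f"no bond parameters for {key}")
        return self.bond_types[key]

    def resolve_angle(self, t: tuple[str, str, str]) -> tuple[float, float]:
        key = _canon_angle(t)
        if key not in self.angle_types:
            raise ParameterLookupError(f"no angle parameters for {key}")
        return self.angle_types[key]

    def resolve_dihedral(
        self, t: tuple[str, str, str, str], variant_tag: str = ""
    ) -> tuple[float, float, float, float]:
        key = _canon_dihedral(t)
        if variant_tag:
            tagged = f"{key}:{variant_tag}"
            if tagged in self.dihedral_types:
                return self.dihedral_types[tagged]
        if key not in self.dihedral_types:
            raise ParameterLookupError(f"no torsion parameters for {key}")
        return self.dihedral_types[key]


# ---------------------------------------------------------------------------
# Parameter transformations
# ---------------------------------------------------------------------------


def scale_epsilon(params: ForceFieldParameters, factor: float) -> ForceFieldParameters:
    """All atom-type epsilons multiplied by ``factor``; sigma untouched."""
    if factor <= 0:
        raise ValueError("epsilon scale factor must be positive")
    out = params.copy()
    for name, at in out.atom_types.items():
        out.atom_types[name] = replace(at, epsilon=at.epsilon * factor)
        out.provenance[f"atomtype:{name}"] = (
            out.provenance.get(f"atomtype:{name}", "original-OPLS")
            + f" | scaled(eps x {factor:g})"
        )
    return out


def scale_charges(params: ForceFieldParameters, factor: float = 0.85) -> ForceFieldParameters:
    """Uniform charge depolarization: every partial charge times ``factor``.

    Scaling a zero-sum charge vector preserves neutrality exactly.
    """
    if not (0 < factor <= 1):
        raise ValueError("charge scale factor must be in (0, 1]")
    out = params.copy()
    for name, at in out.atom_types.items():
        out.atom_types[name] = replace(at, charge=at.charge * factor)
    for name in out.atom_charges:
        out.atom_charges[name] *= factor
    out.provenance["charges"] = (
        out.provenance.get("charges", "original-OPLS") + f" | scaled(q x {factor:g})"
    )
    return out


def set_hydroxyl_npa_charges(
    params: ForceFieldParameters,
    q_o: float = ref.NPA_HYDROXYL_CHARGES["O"],
    q_h: float = ref.NPA_HYDROXYL_CHARGES["HO"],
    repair_atom: str = "C1",
) -> ForceFieldParameters:
    """Replace hydroxyl O/H charges by NPA values, repairing neutrality.

    The residual charge created by the substitution is added to
    ``repair_atom`` (the carbinol carbon by default), so the molecule stays
    exactly neutral.
    """
    if repair_atom in ("O1", "HO1"):
        raise ValueError("repair atom must not be the hydroxyl O or H")
    if repair_atom not in params.atom_charges:
        raise KeyError(f"repair atom {repair_atom!r} not in charge table")
    out = params.copy()
    residual = (out.atom_charges["O1"] + out.atom_charges["HO1"]) - (q_o + q_h)
    out.atom_charges["O1"] = q_o
    out.atom_charges["HO1"] = q_h
    out.atom_charges[repair_atom] += residual
    out.provenance["charges"] = (
        out.provenance.get("charges", "original-OPLS")
        + f" | NPA hydroxyl ({q_o:g}/{q_h:g}), repair on {repair_atom}"
    )
    return out


# ---------------------------------------------------------------------------
# Fourier <-> Ryckaert-Bellemans
# ---------------------------------------------------------------------------


def fourier_to_rb(v) -> tuple[float, float, float, float, float, float]:
    """OPLS Fourier coefficients -> RB polynomial coefficients C0..C5."""
    v1, v2, v3, v4 = v
    return (
        v2 + 0.5 * (v1 + v3),
        0.5 * (-v1 + 3.0 * v3),
        -v2 + 4.0 * v4,
        -2.0 * v3,
        -4.0 * v4,
        0.0,
    )


def rb_to_fourier(c) -> tuple[float, float, float, float]:
    """RB coefficients C0..C5 -> OPLS Fourier V1..V4 (constant offset dropped)."""
    c0, c1, c2, c3, c4, c5 = c
    if abs(c5) > 1e-9:
        raise ValueError("C5 != 0: not representable as a 4-term OPLS series")
    v3 = -0.5 * c3
    v1 = -2.0 * c1 - 1.5 * c3
    v4 = -0.25 * c4
    v2 = -c2 - c4
    return (v1, v2, v3, v4)


# ---------------------------------------------------------------------------
# Menthol molecule
# ---------------------------------------------------------------------------

# Heavy atoms first (C1..C10, O1, HO1), then the 19 aliphatic hydrogens.
# Ring: C1-C2-C3-C4-C5-C6.  OH on C1, isopropyl (C7 with methyls C8, C9)
# on C2, methyl C10 on C5 — all equatorial (the menthol diastereomer).
MENTHOL_ATOM_NAMES = [
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9", "C10",
    "O1", "HO1",
    "H1", "H2", "H3A", "H3B", "H4A", "H4B", "H5", "H6A", "H6B", "H7",
    "H8A", "H8B", "H8C", "H9A", "H9B", "H9C", "H10A", "H10B", "H10C",
]

_TYPE_BY_NAME = {
    name: ("O" if name == "O1" else "HO" if name == "HO1" else
           "CT" if name.startswith("C") else "HC")
    for name in MENTHOL_ATOM_NAMES
}

_IDX = {name: i for i, name in enumerate(MENTHOL_ATOM_NAMES)}

MENTHOL_BONDS = [
    # ring
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "C6"), ("C6", "C1"),
    # hydroxyl
    ("C1", "O1"), ("O1", "HO1"),
    # isopropyl
    ("C2", "C7"), ("C7", "C8"), ("C7", "C9"),
    # ring methyl
    ("C5", "C10"),
    # hydrogens
    ("C1", "H1"), ("C2", "H2"), ("C3", "H3A"), ("C3", "H3B"),
    ("C4", "H4A"), ("C4", "H4B"), ("C5", "H5"), ("C6", "H6A"), ("C6", "H6B"),
    ("C7", "H7"),
    ("C8", "H8A"), ("C8", "H8B"), ("C8", "H8C"),
    ("C9", "H9A"), ("C9", "H9B"), ("C9", "H9C"),
    ("C10", "H10A"), ("C10", "H10B"), ("C10", "H10C"),
]

#: Central bond of the separately refit isopropyl torsions.
_IPR_BOND = frozenset((_IDX["C2"], _IDX["C7"]))

_ROLE_BY_NAME = {
    "C1": "carbinol_C", "C2": "CH_C", "C3": "CH2_C", "C4": "CH2_C",
    "C5": "CH_C", "C6": "CH2_C", "C7": "CH_C", "C8": "CH3_C",
    "C9": "CH3_C", "C10": "CH3_C", "O1": "alcohol_O", "HO1": "alcohol_H",
}


def _original_charges() -> dict[str, float]:
    q = {}
    for name in MENTHOL_ATOM_NAMES:
        role = _ROLE_BY_NAME.get(name, "aliphatic_H")
        q[name] = ref.OPLS_ROLE_CHARGES[role]
    return q


def _base_parameters(variant: str) -> ForceFieldParameters:
    if variant not in ("original", "published"):
        raise ValueError("variant must be 'original' or 'published'")
    eps = ref.EPSILON_ORIGINAL if variant == "original" else ref.EPSILON_PUBLISHED
    atom_types = {
        name: AtomType(name, ref.LJ_SIGMA_NM[name], eps[name], 0.0, ref.ATOM_MASSES[name])
        for name in ("CT", "HC", "O", "HO")
    }
    dihedrals = dict(
        ref.DIHEDRAL_TYPES_ORIGINAL if variant == "original"
        else ref.DIHEDRAL_TYPES_PUBLISHED
    )
    prov = {f"atomtype:{n}": ("original-OPLS" if variant == "original"
                              else "original-OPLS | scaled(eps x 1.1875)")
            for n in atom_types}
    for key in dihedrals:
        prov[f"dihedral:{key}"] = (
            "original-OPLS" if variant == "original"
            else ref.DIHEDRAL_PROVENANCE.get(key, "original-OPLS")
        )
    for key in ref.BOND_TYPES:
        prov[f"bond:{'-'.join(key)}"] = "original-OPLS"
    for key in ref.ANGLE_TYPES:
        prov[f"angle:{'-'.join(key)}"] = "original-OPLS"
    params = ForceFieldParameters(
        atom_types=atom_types,
        bond_types=dict(ref.BOND_TYPES),
        angle_types=dict(ref.ANGLE_TYPES),
        dihedral_types=dihedrals,
        atom_charges=_original_charges(),
        provenance=prov,
    )
    params.provenance["charges"] = "original-OPLS"
    if variant == "published":
        params = set_hydroxyl_npa_charges(params)
        params = scale_charges(params, ref.CHARGE_SCALE_FACTOR)
    return params


def _menthol_topology(params: ForceFieldParameters) -> MolecularTopology:
    from .forcefield_core import enumerate_angles, enumerate_dihedrals

    names = MENTHOL_ATOM_NAMES
    atoms = [
        Atom(n, params.atom_types[_TYPE_BY_NAME[n]], params.atom_charges[n])
        for n in names
    ]
    bond_idx = [(_IDX[a], _IDX[b]) for a, b in MENTHOL_BONDS]
    bonds = []
    for i, j in bond_idx:
        r_eq, k_r = params.resolve_bond(_TYPE_BY_NAME[names[i]], _TYPE_BY_NAME[names[j]])
        bonds.append(BondTerm(i, j, r_eq, k_r))
    angles = []
    for i, j, k in enumerate_angles(len(names), bond_idx):
        th, kt = params.resolve_angle(
            (_TYPE_BY_NAME[names[i]], _TYPE_BY_NAME[names[j]], _TYPE_BY_NAME[names[k]])
        )
        angles.append(AngleTerm(i, j, k, th, kt))
    dihedrals = []
    for i, j, k, l in enumerate_dihedrals(len(names), bond_idx):
        tag = "ipr" if frozenset((j, k)) == _IPR_BOND else ""
        tt = tuple(_TYPE_BY_NAME[names[a]] for a in (i, j, k, l))
        v = params.resolve_dihedral(tt, variant_tag=tag)
        key = _canon_dihedral(tt) + (f":{tag}" if tag and f"{_canon_dihedral(tt)}:{tag}" in params.dihedral_types else "")
        dihedrals.append(DihedralTerm(i, j, k, l, *v, type_key=key))
    top = MolecularTopology(atoms, bonds, angles, dihedrals)
    top.validate()
    return top


def _nerf_place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Position of atom d bonded to c with given internal coordinates."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(phi),
         bond * math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _profile_minimum_deg(v) -> float:
    grid = np.arange(0.0, 360.0, 1.0)
    return float(grid[np.argmin(fourier_energy(v, grid))])


def _menthol_conformation(params: ForceFieldParameters) -> Conformation:
    """Idealized chair conformer from equilibrium bond lengths and angles.

    Ring geometry is the analytic chair with CT-CT-CT angles at their
    equilibrium value; the three substituents sit equatorial; hydroxyl and
    isopropyl torsions are set at the minima of their torsion profiles.
    """
    b_cc, _ = params.resolve_bond("CT", "CT")
    b_ch, _ = params.resolve_bond("CT", "HC")
    b_co, _ = params.resolve_bond("CT", "O")
    b_oh, _ = params.resolve_bond("HO", "O")
    th_ccc, _ = params.resolve_angle(("CT", "CT", "CT"))
    th_cch, _ = params.resolve_angle(("CT", "CT", "HC"))
    th_coh, _ = params.resolve_angle(("CT", "O", "HO"))
    th_hch, _ = params.resolve_angle(("HC", "CT", "HC"))

    # Analytic chair: ring atoms at radius rho, alternating +/- zd.
    cosa = math.cos(math.radians(th_ccc))
    zd2_over_rho2 = (0.5 + cosa) / (4.0 * (1.0 - cosa))
    rho = b_cc / math.sqrt(1.0 + 4.0 * zd2_over_rho2)
    zd = rho * math.sqrt(zd2_over_rho2)
    x = np.zeros((len(MENTHOL_ATOM_NAMES), 3))
    for i in range(6):
        ang = math.radians(60.0 * i)
        x[i] = (rho * math.cos(ang), rho * math.sin(ang), zd * (-1) ** i)

    def subst_dirs(ci: int, na: int, nb: int, half_angle_deg: float):
        e1 = x[na] - x[ci]
        e1 /= np.linalg.norm(e1)
        e2 = x[nb] - x[ci]
        e2 /= np.linalg.norm(e2)
        bis = -(e1 + e2)
        bis /= np.linalg.norm(bis)
        perp = np.cross(e1, e2)
        perp /= np.linalg.norm(perp)
        g = math.radians(half_angle_deg)
        d1 = bis * math.cos(g) + perp * math.sin(g)
        d2 = bis * math.cos(g) - perp * math.sin(g)
        # axial direction is the one more parallel to the ring axis (z)
        if abs(d1[2]) >= abs(d2[2]):
            return d2, d1  # (equatorial, axial)
        return d1, d2

    half_hh = th_hch / 2.0
    ring_nbrs = {0: (1, 5), 1: (2, 0), 2: (3, 1), 3: (4, 2), 4: (5, 3), 5: (0, 4)}

    # C1: hydroxyl equatorial, H axial
    eq, ax = subst_dirs(0, *ring_nbrs[0], half_hh)
    x[_IDX["O1"]] = x[0] + eq * b_co
    x[_IDX["H1"]] = x[0] + ax * b_ch
    # C2: isopropyl equatorial
    eq, ax = subst_dirs(1, *ring_nbrs[1], half_hh)
    x[_IDX["C7"]] = x[1] + eq * b_cc
    x[_IDX["H2"]] = x[1] + ax * b_ch
    # C5: methyl equatorial
    eq, ax = subst_dirs(4, *ring_nbrs[4], half_hh)
    x[_IDX["C10"]] = x[4] + eq * b_cc
    x[_IDX["H5"]] = x[4] + ax * b_ch
    # CH2 carbons: two hydrogens
    for ci, (ha, hb) in ((2, ("H3A", "H3B")), (3, ("H4A", "H4B")), (5, ("H6A", "H6B"))):
        eq, ax = subst_dirs(ci, *ring_nbrs[ci], half_hh)
        x[_IDX[ha]] = x[ci] + eq * b_ch
        x[_IDX[hb]] = x[ci] + ax * b_ch

    # Hydroxyl hydrogen at the minimum of the C-C-O-H torsion profile.
    phi_oh = _profile_minimum_deg(params.resolve_dihedral(("CT", "CT", "O", "HO")))
    x[_IDX["HO1"]] = _nerf_place(x[1], x[0], x[_IDX["O1"]], b_oh, th_coh, phi_oh)

    # Isopropyl: methyls staggered around the profile minimum.
    phi_ipr = _profile_minimum_deg(
        params.resolve_dihedral(("CT", "CT", "CT", "CT"), variant_tag="ipr")
    )
    c7 = x[_IDX["C7"]]
    x[_IDX["C8"]] = _nerf_place(x[0], x[1], c7, b_cc, th_ccc, phi_ipr)
    x[_IDX["C9"]] = _nerf_place(x[0], x[1], c7, b_cc, th_ccc, phi_ipr + 120.0)
    x[_IDX["H7"]] = _nerf_place(x[0], x[1], c7, b_ch, th_cch, phi_ipr - 120.0)

    # Methyl hydrogens, staggered.
    for carbon, ref_a, hs in (
        ("C8", "C2", ("H8A", "H8B", "H8C")),
        ("C9", "C2", ("H9A", "H9B", "H9C")),
        ("C10", "C4", ("H10A", "H10B", "H10C")),
    ):
        prev = {"C8": "C7", "C9": "C7", "C10": "C5"}[carbon]
        for h, phi in zip(hs, (180.0, 60.0, -60.0)):
            x[_IDX[h]] = _nerf_place(
                x[_IDX[ref_a]], x[_IDX[prev]], x[_IDX[carbon]], b_ch, th_cch, phi
            )
    return Conformation(x)


def build_menthol(
    variant: str = "published",
) -> tuple[MolecularTopology, ForceFieldParameters, Conformation]:
    """Menthol topology, parameters and idealized chair conformation.

    ``variant='published'`` carries the final parameter set (refit torsions,
    epsilon at 118.75 % of OPLS-AA, NPA hydroxyl charges depolarized to
    85 %); ``variant='original'`` carries unmodified OPLS-AA values.
    """
    params = _base_parameters(variant)
    top = _menthol_topology(params)
    conf = _menthol_conformation(params)
    return top, params, conf


# ---------------------------------------------------------------------------
# GROMACS .itp write / read
# ---------------------------------------------------------------------------


def write_topology(
    top: MolecularTopology,
    params: ForceFieldParameters,
    path,
    molecule_name: str = "MNT",
) -> None:
    """Write a GROMACS .itp with RB (funct 3) torsions and explicit 1-4 pairs."""
    lines = []
    lines.append("[ atomtypes ]")
    lines.append("; name      mass     charge  ptype      sigma    epsilon")
    for name, at in params.atom_types.items():
        lines.append(
            f"  {name:<6s} {at.mass:9.4f} {at.charge:10.6f}  A "
            f"{at.sigma:12.8f} {at.epsilon:12.8f}"
        )
    lines.append("")
    lines.append("[ moleculetype ]")
    lines.append("; name  nrexcl")
    lines.append(f"{molecule_name}  3")
    lines.append("")
    lines.append("[ atoms ]")
    lines.append(";  nr  type  resnr  residue  atom  cgnr     charge      mass")
    for n, a in enumerate(top.atoms, start=1):
        lines.append(
            f"{n:5d}  {a.type.name:<4s} 1  {molecule_name}  {a.name:<5s} {n:4d} "
            f"{a.charge:11.6f} {a.type.mass:10.4f}"
        )
    lines.append("")
    lines.append("[ bonds ]")
    lines.append(";  i    j  funct       r_eq          k_r")
    for b in top.bonds:
        lines.append(f"{b.i + 1:5d} {b.j + 1:5d}  1 {b.r_eq:12.6f} {b.k_r:14.2f}")
    lines.append("")
    lines.append("[ pairs ]")
    lines.append(";  i    j  funct")
    for pair in sorted(top.pairs14, key=sorted):
        i, j = sorted(pair)
        lines.append(f"{i + 1:5d} {j + 1:5d}  1")
    lines.append("")
    lines.append("[ angles ]")
    lines.append(";  i    j    k  funct   theta_eq    k_theta")
    for a in top.angles:
        lines.append(
            f"{a.i + 1:5d} {a.j + 1:5d} {a.k + 1:5d}  1 {a.theta_eq:10.3f} {a.k_theta:10.3f}"
        )
    lines.append("")
    lines.append("[ dihedrals ]")
    lines.append(";  i    j    k    l  funct      C0 .. C5 (Ryckaert-Bellemans)")
    for d in top.dihedrals:
        c = fourier_to_rb(d.coefficients)
        cs = " ".join(f"{ci:12.8f}" for ci in c)
        lines.append(f"{d.i + 1:5d} {d.j + 1:5d} {d.k + 1:5d} {d.l + 1:5d}  3 {cs}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


_KNOWN_SECTIONS = {"atomtypes", "moleculetype", "atoms", "bonds", "pairs", "angles", "dihedrals"}


def read_topology(path) -> tuple[MolecularTopology, ForceFieldParameters]:
    """Parse a topology written by :func:`write_topology`."""
    atom_types: dict[str, AtomType] = {}
    atoms: list[Atom] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    dihedrals: list[DihedralTerm] = []
    pairs14: set[frozenset[int]] = set()
    atom_charges: dict[str, float] = {}
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] \t").lower()
                if section not in _KNOWN_SECTIONS:
                    raise ParseError(f"line {lineno}: unknown directive [ {section} ]")
                continue
            parts = line.split()
            try:
                if section == "atomtypes":
                    name, mass, charge, _pt, sigma, eps = parts[:6]
                    atom_types[name] = AtomType(
                        name, float(sigma), float(eps), float(charge), float(mass)
                    )
                elif section == "moleculetype":
                    continue
                elif section == "atoms":
                    _nr, tname, _resnr, _res, aname, _cg, q = parts[:7]
                    if tname not in atom_types:
                        raise ParameterLookupError(
                            f"line {lineno}: atom type {tname!r} not defined"
                        )
                    atoms.append(Atom(aname, atom_types[tname], float(q)))
                    atom_charges[aname] = float(q)
                elif section == "bonds":
                    i, j, funct, r_eq, k_r = parts[:5]
                    if funct != "1":
                        raise ParseError(f"line {lineno}: unsupported bond funct {funct}")
                    bonds.append(BondTerm(int(i) - 1, int(j) - 1, float(r_eq), float(k_r)))
                elif section == "pairs":
                    i, j = int(parts[0]) - 1, int(parts[1]) - 1
                    pairs14.add(frozenset((i, j)))
                elif section == "angles":
                    i, j, k, funct, th, kt = parts[:6]
                    if funct != "1":
                        raise ParseError(f"line {lineno}: unsupported angle funct {funct}")
                    angles.append(
                        AngleTerm(int(i) - 1, int(j) - 1, int(k) - 1, float(th), float(kt))
                    )
                elif section == "dihedrals":
                    i, j, k, l, funct = parts[:5]
                    if funct != "3":
                        raise ParseError(f"line {lineno}: unsupported dihedral funct {funct}")
                    c = tuple(float(p) for p in parts[5:11])
                    v = rb_to_fourier(c)
                    dihedrals.append(
                        DihedralTerm(int(i) - 1, int(j) - 1, int(k) - 1, int(l) - 1, *v)
                    )
                elif section is None:
                    raise ParseError(f"line {lineno}: content before any directive")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc

    top = MolecularTopology(atoms, bonds, angles, dihedrals, pairs14=pairs14)
    params = ForceFieldParameters(
        atom_types=atom_types,
        bond_types={},
        angle_types={},
        dihedral_types={},
        atom_charges=atom_charges,
        provenance={"source": "read from file"},
    )
    return top, params
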