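"""Conformation I/O: PDB and GRO files via MDAnalysis.

Coordinates are nm internally; PDB files are Angstrom and GRO files nm on
disk — MDAnalysis handles the file-level conventions, the nm conversion
happens here at the boundary.
"""

from __future__ import annotations

import warnings

import numpy as np

from .forcefield_core import Conformation, MolecularTopology
from .units import ANGSTROM_TO_NM

__all__ = ["read_conformation", "write_conformation"]


def read_conformation(path) -> Conformation:
    """Read atom coordinates [nm] from a .pdb or .gro file (atom order kept)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = u.atoms.positions * ANGSTROM_TO_NM  # MDAnalysis works in Angstrom
    return Conformation(np.asarray(coords, dtype=float))


def write_conformation(
    conf: Conformation,
    path,
    top: MolecularTopology | None = None,
    residue_name: str = "MNT",
) -> None:
    """Write coordinates to .pdb or .gro; atom names taken from ``top`` if given."""
    import MDAnalysis as mda

    n = conf.n_atoms
    names = (
        [a.name for a in top.atoms]
        if top is not None and top.n_atoms == n
        else [f"X{i + 1}" for i in range(n)]
    )
    elements = [nm[0] for nm in names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", elements)
        u.add_TopologyAttr("resnames", [residue_name])
        u.add_TopologyAttr("resids", [1])
        u.atoms.positions = conf.coordinates / ANGSTROM_TO_NM
        u.dimensions = [100.0, 100.0, 100.0, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))
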