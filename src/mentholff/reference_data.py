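"""Published menthol force-field parameter set and literature property values.

Numeric tables from the published menthol OPLS-AA reparameterization:
Lennard-Jones types, harmonic bond/angle constants, Fourier torsion
coefficients (both the original OPLS-AA values and the refit hydroxyl /
isopropyl torsions), and the experimental-vs-calculated liquid-property
comparison used for validation worked examples.

Units here are the package internal units (nm, kJ/mol, e, u) after
conversion from the published table units (sigma printed in Angstrom,
bond force constants printed with a 10^3 multiplier).
"""

from __future__ import annotations

from .units import ANGSTROM_TO_NM

# -- Lennard-Jones atom types -----------------------------------------------
# name -> (sigma [nm], epsilon [kJ/mol], mass [u])
# "published": the final, epsilon-scaled values as printed.
# "original": unmodified OPLS-AA epsilon (sigma identical in both sets).

LJ_SIGMA_NM = {
    "CT": 3.50 * ANGSTROM_TO_NM,
    "HC": 2.50 * ANGSTROM_TO_NM,
    "O": 3.12 * ANGSTROM_TO_NM,
    "HO": 0.0,
}

EPSILON_PUBLISHED = {"CT": 0.327921, "HC": 0.149055, "O": 0.844645, "HO": 0.0}
EPSILON_ORIGINAL = {"CT": 0.276144, "HC": 0.125520, "O": 0.711280, "HO": 0.0}

#: Scaling factor relating the two epsilon sets (118.75 % of original).
EPSILON_SCALE_FACTOR = 1.1875

#: Uniform charge-depolarization factor of the final parameter set.
CHARGE_SCALE_FACTOR = 0.85

ATOM_MASSES = {"CT": 12.011, "HC": 1.008, "O": 15.9994, "HO": 1.008}

# -- Bond stretching: type pair -> (r_eq [nm], k_r [kJ/mol/nm^2]) -----------
# Printed r_eq in Angstrom and K_r with a 10^3 multiplier; converted here.

BOND_TYPES = {
    ("CT", "CT"): (0.1529, 224262.4),
    ("CT", "HC"): (0.1090, 284512.0),
    ("CT", "O"): (0.1410, 267776.0),
    ("HO", "O"): (0.0945, 462750.4),
}

# -- Angle bending: type triple -> (theta_eq [deg], k_theta [kJ/mol/rad^2]) --

ANGLE_TYPES = {
    ("HC", "CT", "HC"): (107.8, 276.144),
    ("CT", "CT", "HC"): (110.7, 313.800),
    ("CT", "CT", "CT"): (112.7, 488.273),
    ("CT", "CT", "O"): (109.5, 418.400),
    ("CT", "O", "HO"): (108.5, 460.240),
    ("HC", "CT", "O"): (109.5, 292.880),
}

# -- Torsions: canonical type string -> (V1, V2, V3, V4) [kJ/mol] -----------
# The ":ipr" entries apply only to torsions whose central bond is the
# ring-carbon / isopropyl-carbon bond; they were refit separately.

DIHEDRAL_TYPES_PUBLISHED = {
    "CT-CT-CT-CT": (-3.3472, -0.2092, 0.8368, 0.0),
    "CT-CT-CT-HC": (-7.531, 0.000, -1.255, 0.0),
    "HC-CT-CT-HC": (-7.531, 0.000, -1.255, 0.0),
    "CT-CT-CT-O": (7.159, -2.092, 2.774, 0.0),
    "HC-CT-CT-O": (-0.00002, 0.000, 1.958, 0.0),
    "HC-CT-O-HO": (0.000, 0.000, 0.000, 0.0),
    "CT-CT-O-HO": (7.448, -1.430, 7.261, 0.0),
    "CT-CT-CT-CT:ipr": (12.681, -1.557, 2.934, 0.0),
    "CT-CT-CT-HC:ipr": (0.000, 0.000, 0.000, 0.0),
    "HC-CT-CT-HC:ipr": (0.000, 0.000, 0.000, 0.0),
}

#: Provenance of each published torsion row: refit in the parameterization
#: work, or carried over from the original OPLS-AA force field.
DIHEDRAL_PROVENANCE = {
    "CT-CT-CT-CT": "original-OPLS",
    "CT-CT-CT-HC": "original-OPLS",
    "HC-CT-CT-HC": "original-OPLS",
    "CT-CT-CT-O": "fitted-this-work",
    "HC-CT-CT-O": "fitted-this-work",
    "HC-CT-O-HO": "fitted-this-work",
    "CT-CT-O-HO": "fitted-this-work",
    "CT-CT-CT-CT:ipr": "fitted-this-work",
    "CT-CT-CT-HC:ipr": "fitted-this-work",
    "HC-CT-CT-HC:ipr": "fitted-this-work",
}

# The original OPLS-AA values of the refit alcohol torsions are not part of
# the published table; these are the standard OPLS-AA alcohol values
# (reconstruction, used only by the "original" parameter variant).
DIHEDRAL_TYPES_ORIGINAL = {
    "CT-CT-CT-CT": (-3.3472, -0.2092, 0.8368, 0.0),
    "CT-CT-CT-HC": (-7.531, 0.000, -1.255, 0.0),
    "HC-CT-CT-HC": (-7.531, 0.000, -1.255, 0.0),
    "CT-CT-CT-O": (7.159, -2.092, 2.774, 0.0),
    "HC-CT-CT-O": (0.000, 0.000, 1.958, 0.0),
    "HC-CT-O-HO": (0.000, 0.000, 1.8828, 0.0),
    "CT-CT-O-HO": (-1.4895, -0.7280, 2.0585, 0.0),
}

# -- Partial charges ---------------------------------------------------------
# Standard OPLS-AA aliphatic/alcohol charges by chemical role.  Per-atom
# charges of the published set are derived from these: hydroxyl O/H replaced
# by NPA values (with a neutrality repair on the carbinol carbon), then all
# charges depolarized by CHARGE_SCALE_FACTOR.

OPLS_ROLE_CHARGES = {
    "carbinol_C": 0.205,
    "CH_C": -0.06,
    "CH2_C": -0.12,
    "CH3_C": -0.18,
    "alcohol_O": -0.683,
    "alcohol_H": 0.418,
    "aliphatic_H": 0.06,
}

#: Hydroxyl charges from natural population analysis, before depolarization.
NPA_HYDROXYL_CHARGES = {"O": -0.72, "HO": 0.45}

# -- Validation worked examples ---------------------------------------------
# (property, T [K]) -> (experimental, calculated, SD, printed % deviation)
# as published for the final force field.

PROPERTY_COMPARISON = {
    ("density", 293): (890.0, 921.1, 1.1, 3.49),
    ("density", 298): (923.6, 917.3, 1.2, 0.68),
    ("density", 318): (889.0, 902.0, 3.4, 1.46),
    ("density", 353): (877.0, 872.1, 3.5, 0.56),
    ("density", 393): (865.1, 836.4, 3.8, 3.32),
    ("surface_tension", 313): (31.61, 28.6, 8.2, 9.52),
    ("surface_tension", 333): (29.2, 27.1, 6.5, 7.19),
    ("surface_tension", 353): (27.82, 24.9, 5.4, 10.50),
    ("surface_tension", 373): (25.62, 22.7, 3.6, 11.40),
    ("surface_tension", 393): (23.75, 20.6, 3.0, 13.26),
    ("hvap", 382): (56.92, 52.8, 5.7, 7.24),
    ("hvap", 421): (53.42, 51.1, 4.8, 4.34),
    ("hvap", 473): (48.42, 49.5, 5.5, 2.23),
    ("viscosity", 320): (10.8, 5.9, 1.2, 45.37),
    ("viscosity", 350): (2.3, 3.8, 0.58, 65.22),
    ("viscosity", 380): (0.83, 2.8, 0.36, 237.4),
}

# Same comparison for the unmodified OPLS-AA parameter set
# (property, T) -> (experimental, calculated, printed % relative error).
PROPERTY_COMPARISON_STANDARD_OPLS = {
    ("density", 293): (890.0, 896.1, 0.7),
    ("density", 318): (889.0, 875.0, 1.6),
    ("density", 393): (865.1, 801.8, 7.3),
    ("hvap", 382): (56.92, 31.9, 44.0),
    ("hvap", 421): (53.42, 29.7, 44.4),
    ("hvap", 473): (48.42, 26.7, 44.9),
}
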