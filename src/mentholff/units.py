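"""Unit system and physical constants.

Internal units follow the GROMACS convention: lengths in nm, time in ps,
energies in kJ/mol, charges in elementary charges (e), masses in u,
temperature in K, pressure in bar.  Everything crossing the package boundary
in another unit (Angstrom coordinates in PDB files, hartree QM energies,
bar*nm surface-tension integrands) is converted here and nowhere else.
"""

#: Coulomb conversion factor, kJ mol^-1 nm e^-2 (1/(4 pi eps0) in MD units).
KE_COULOMB = 138.935458

#: Molar gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314462e-3

#: One hartree in kJ/mol.
HARTREE_TO_KJMOL = 2625.499639

#: Surface-tension integrand conversion: 1 bar*nm = 0.1 mN/m.
BAR_NM_TO_MN_PER_M = 0.1

#: Viscosity conversion: 1 (kg m^-3) * nm^2 / ps = 1e-3 mPa*s.
KGM3_NM2_PER_PS_TO_MPAS = 1.0e-3

#: Angstrom -> nm.
ANGSTROM_TO_NM = 0.1
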