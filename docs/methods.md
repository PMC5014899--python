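# Methods

## Scope and model

`mentholff` implements the classical-force-field side of a menthol
parameterization workflow: the intramolecular OPLS-AA potential, torsion
refitting against quantum-chemical scan energies, the parameter
transformations that produce the final published menthol set, and the
post-processing estimators used to validate such a force field against
liquid properties.  It deliberately contains no MD engine and no quantum
chemistry: trajectories and QM scan energies are *inputs*, consumed as
time series or angle/energy tables.

### Intramolecular potential

For a single molecule the energy is

    E = Σ_bonds  ½ k_r (r − r_eq)²
      + Σ_angles ½ k_θ (θ − θ_eq)²
      + Σ_torsions ½ [V1(1+cos φ) + V2(1−cos 2φ) + V3(1+cos 3φ) + V4(1−cos 4φ)]
      + Σ_pairs  s_ij { 4 ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶] + k_e q_i q_j / r }

with geometric-mean combining (σ_ij = √(σ_i σ_j), ε_ij = √(ε_i ε_j)),
s_ij = 0 for pairs separated by one or two bonds, ½ for 1-4 pairs and 1
otherwise — the OPLS-AA conventions.  Units are GROMACS-style throughout:
nm, ps, kJ/mol, e, u, K, bar; σ values published in Å are divided by 10 on
ingest, and bond force constants published with a 10³ multiplier are
expanded (e.g. the C–C value 224.2624 becomes 224 262.4 kJ mol⁻¹ nm⁻²).
The electric conversion factor is k_e = 138.935458 kJ nm mol⁻¹ e⁻².

Pair classification uses shortest bond-graph distance, so in the
cyclohexane ring a pair that is 1-4 along one arc and 1-3 along the other
is excluded, not half-scaled.  An independent brute-force implementation
of the whole sum (explicit loops, Floyd–Warshall distances) lives in the
test suite and must agree with the vectorized evaluator to 1e-9 kJ/mol.

The published table of the menthol parameter set does not print the
torsion functional form; the ½-prefactor OPLS 4-term Fourier series above
is assumed, which is the standard OPLS-in-GROMACS convention and is
consistent with the Ryckaert–Bellemans representation used in the
distributed topology.

Analytic forces are implemented for every term and are verified against
central finite differences (1e-6 relative).  The steepest-descent
minimizer uses an adaptive step (largest per-atom displacement, initial
0.01 nm, ×1.2 on an accepted step, ×0.5 on a rejected one) and stops when
every atomic force norm is below the threshold, default 200 kJ mol⁻¹ nm⁻¹.
The threshold the original workflow prints carries a force-constant unit
(kJ mol⁻¹ nm⁻²); since convergence criteria act on forces, it is read here
as a force.

### Torsion refitting

A scan drives one torsion over [0°, 360°) in 10° steps by rigidly rotating
the connected component on one side of the central bond; the 360° point
duplicates 0° and is not double-counted.  The fitting target is

    residual(α) + Σ_inst E_dih(V; φ_inst(α)) + c  ≈  ΔE_QM(α),

where the residual is the full intramolecular energy minus the
contribution of the fitted torsion *type* on the driven bond.  Every
instance of that type on the bond enters the design (e.g. two C-C-O-H
instances for the hydroxyl rotor, four C-C-C-C instances for the
isopropyl bond), and coefficients are per type.  The model is linear in
(V1..V4, c), so the fit is ordinary least squares, with coefficient
standard errors from σ̂²(XᵀX)⁻¹.  A literal reading of the published
objective — a *signed* sum of differences — is unbounded below; least
squares is the standard reading of torsion fitting and is what is
implemented (a least-absolute-deviations option exists behind
`loss="l1"`).

Rather than re-zeroing both profiles to their minima (which makes the
objective non-smooth), a free constant offset c is fitted; reports
re-zero each curve to its own minimum afterwards.  The design keeps V4
even though the published set has V4 = 0 everywhere; `freeze_v4=True`
removes it.  Rank deficiency (e.g. a 60° grid, on which cos 4φ aliases
cos 2φ) raises an error naming the unresolvable harmonics instead of
returning an arbitrary solution.

Whether the original work fitted the hydroxyl and isopropyl scans jointly
or sequentially is not stated; scans here are independent per bond and
can be run in any order.

### Property estimators

*Surface tension* of a two-interface slab:
γ = 0.5 L_z (⟨P_zz⟩ − (⟨P_xx⟩+⟨P_yy⟩)/2), converted from bar·nm with
×0.1 to mN/m.  The validation study prints the tangential term as
(⟨P_xx⟩−⟨P_yy⟩)/2, which is zero on average by x/y symmetry and cannot
produce the reported values; the standard form is the default and the
printed variant sits behind `strict_paper=True`.

*Enthalpy of vaporization*: ΔH_vap = E(g) − E(l)/N + R T, assuming equal
kinetic and vibrational energy in both phases, with R = 8.314462×10⁻³
kJ mol⁻¹ K⁻¹ and extensive liquid energies divided by the molecule count
(the published formula implies but does not state this division).  Gas
input must be a single molecule, and a phase-temperature mismatch beyond
0.5 K is an error.

*Shear viscosity* by the periodic perturbation method: a cosine
acceleration a_x(z) = A cos(2πz/L_z) drives a steady velocity field whose
mass-weighted amplitude is estimated per frame as
V(t) = 2 Σ m_i v_{i,x} cos(k z_i) / Σ m_i, k = 2π/L_z, and
η = A ρ / ⟨V⟩ · (L_z/2π)², converted to mPa·s with ×10⁻³.  ⟨V⟩ is the
plain mean of the amplitude series after an equilibration cut (default:
the first 10 % of frames); no exponential-approach fit is attempted.  The
source study quotes two amplitudes (0.005 and 0.05 nm ps⁻²) in different
sections, so A is always an explicit argument and never defaulted.

*Uncertainties* everywhere are block averages: the series is cut into
non-overlapping 200 ps blocks (trailing partial block dropped) and the SD
of block means is reported.  Viscosity blocks are per-block viscosity
estimates (coef/V̄_block), not a propagated amplitude SD.

### Parameter transformations and topology

The embedded menthol parameter tables carry the published values:
LJ types (published ε = 118.75 % of original OPLS-AA ε; σ unchanged),
harmonic bonds and angles, the original-OPLS torsions, and the refit
hydroxyl/isopropyl torsions, each entry tagged with provenance
(`original-OPLS` / `fitted-this-work` / scaling notes).

Per-atom charges: the published per-atom charge table exists only as a
figure, so non-hydroxyl charges are reconstructed from the standard
OPLS-AA aliphatic values (H +0.06, CH₃ C −0.18, CH₂ C −0.12, CH C −0.06,
carbinol C +0.205 — the standard secondary-carbinol value, which makes
the molecule exactly neutral with the alcohol O/H at −0.683/+0.418).
The published variant replaces the hydroxyl pair by the NPA values
(−0.72/+0.45), adds the +0.005 e neutrality residual to the carbinol
carbon, then depolarizes every charge to 85 %.  Both the repair target
and all charge values are overridable.  These defaults are
reconstructions, not published per-atom numbers.

The embedded conformer is an idealized chair: ring geometry solved
analytically so every C-C bond and C-C-C angle is exactly at equilibrium,
the three substituents equatorial (the menthol diastereomer), hydroxyl
and isopropyl torsions at the minima of their refit profiles, methyls
staggered.  All 31 bonds sit at r_eq to machine precision.

Topology files use the GROMACS .itp dialect: `[atomtypes]` (σ in nm, ε in
kJ/mol), `[atoms]`, `[bonds]`/`[angles]` funct 1, explicit `[pairs]`, and
`[dihedrals]` funct 3 with Ryckaert–Bellemans coefficients
(C0 = V2 + (V1+V3)/2, C1 = (3V3−V1)/2, C2 = 4V4−V2, C3 = −2V3,
C4 = −4V4, C5 = 0), which is lossless for a 4-term Fourier series; the
inverse map drops only the physically irrelevant constant C0.  Numeric
fields are written with 8 decimals and must round-trip to 1e-6.

## Synthetic observables: what they do and do not show

The generators in `synthetic_fixtures` invert each estimator:

* pressure series — component means chosen so the slab formula hits the
  target γ exactly in expectation, with stationary AR(1) noise per
  component (default marginal SD 50 bar, lag-1 correlation 0.3) so block
  averaging faces autocorrelated data; default size 50 000 frames × 2 ps,
  the length of a 100 ns surface-tension production run;
* perturbation run — v_x = V* cos(2πz/L_z) + i.i.d. Gaussian thermal
  noise (default SD 0.45 nm/ps, a carbon-ish thermal velocity at ~320 K)
  with V* = Aρ(L_z/2π)²/η*.  Atom z positions sit on a uniform grid over
  [0, L_z), making the cosine quadrature exact so the zero-noise round
  trip is exact to machine precision (i.i.d. positions would leave an
  O(N^−1/2) bias).  Default 1000 atoms × 1500 frames × 1 ps — a
  deliberately scaled-down stand-in for the 27 000-atom, 10 ns system the
  validation study used;
* energy components — random phase decompositions whose intermolecular
  term absorbs the remainder, so ΔH_vap round-trips exactly;
* torsion scans — residual + Fourier(V) + offset + i.i.d. noise.

These fixtures exercise the estimators' arithmetic, unit conversions and
uncertainty calibration.  They do *not* emulate real MD: no physical
autocorrelation times, no coupling between pressure components, no
hydrodynamic transient in the velocity field, no anharmonic coupling
between scan residuals and the driven torsion.  Passing round trips
therefore validates the estimators as functions of their inputs, not the
ability of any force field to reproduce experiment — the published
absolute property values (density 921.1 kg/m³ at 293 K, γ 28.6 mN/m at
313 K, η 5.9 mPa·s at 320 K, …) require nanosecond-scale MD of hundreds
of molecules in an external engine and are out of scope here; the
exported .itp is designed so such an engine can target them.

## Numerical choices

* Torsion angles: IUPAC sign convention, range (−180°, 180°], measured by
  the atan2 triple-product formula; collinear geometries raise instead of
  returning NaN.  Scan grids are reported in [0°, 360°).
* Scan points whose energy overflows 1e7 kJ/mol (steric clash) are
  flagged and excluded from fits, never silently NaN.
* Least squares via SVD-based `lstsq`; rank tolerance 1e-10 on the
  singular-value ratio.
* Block statistics require ≥ 2 complete blocks and use ddof = 1.
* Hartree inputs convert with 2625.499639 kJ/mol per hartree.

## Problem sizes in the checks

The self-check script (`scripts/acceptance.py`) and the test suite use
36-point scans, 500-replicate fit-coverage calibrations, the default
fixture sizes above, and 200-replicate coverage runs for the estimators —
sizes chosen so the entire suite runs in well under a minute of numerics
while leaving the Monte-Carlo calibrations statistically meaningful.

## Known limitations

* Single-molecule energies only: no periodic boundaries, neighbor lists
  or Ewald electrostatics.
* No atom-typing engine: menthol is built in; other molecules must come
  with an explicit topology file.
* The "original" variant's hydroxyl torsions and all non-hydroxyl charges
  are reconstructions from standard OPLS-AA values, since the source
  publishes neither machine-readably.
* The minimizer is plain steepest descent — robust, but slow near flat
  minima; it is meant for cleaning up idealized geometries, not for
  serious optimization.
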