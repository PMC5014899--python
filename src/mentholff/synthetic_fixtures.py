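"""Synthetic observable generators with known ground truth.

Every estimator in the package has a matching generator here that inverts
it: the generator takes the target value (surface tension, viscosity,
vaporization enthalpy, torsion coefficients), builds a synthetic
observable series around it, and the estimator must recover the target —
exactly at zero noise, within block-average uncertainty otherwise.

Noise models: AR(1) on the pressure-tensor components (so block averaging
has autocorrelation to contend with), i.i.d. Gaussian thermal noise on
atomic velocities and scan energies.  All randomness flows from the
explicit ``seed`` argument; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .forcefield_core import fourier_energy
from .property_estimators import (
    EnergyComponents,
    PerturbationRun,
    PressureTensorSeries,
)
from .torsion_fit import TorsionScan
from .units import BAR_NM_TO_MN_PER_M, KGM3_NM2_PER_PS_TO_MPAS, R_GAS

__all__ = [
    "FixtureSpec",
    "default_residual_profile",
    "make_torsion_scan",
    "make_pressure_series",
    "make_perturbation_run",
    "make_energy_components",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Record of how a fixture was generated: seed, sizes, targets, noise."""

    seed: int
    sizes: tuple
    targets: tuple
    noise: tuple


def default_residual_profile(angles_deg) -> np.ndarray:
    """A smooth, asymmetric stand-in for the non-torsion FF energy terms."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return 2.0 + 0.9 * np.cos(a - 0.6) + 0.4 * np.cos(2.0 * a + 0.3)


def make_torsion_scan(
    v,
    residual_profile=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    step: float = 10.0,
    offset: float = 0.0,
) -> TorsionScan:
    """Scan whose QM column is residual + OPLS Fourier(v) + offset + noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 360.0, float(step))
    residual = (
        np.asarray(residual_profile, dtype=float)
        if residual_profile is not None
        else default_residual_profile(angles)
    )
    if residual.shape != angles.shape:
        raise ValueError("residual profile length mismatch")
    qm = residual + fourier_energy(v, angles) + offset
    if noise_sd > 0:
        qm = qm + rng.normal(0.0, noise_sd, size=angles.shape)
    scan = TorsionScan(
        angles=angles,
        residual_ff_energy=residual,
        qm_energy=qm,
        dihedral_id=(0, 1, 2, 3),
    )
    scan.meta["spec"] = FixtureSpec(
        seed=seed,
        sizes=(len(angles),),
        targets=tuple(float(c) for c in v) + (float(offset),),
        noise=(float(noise_sd),),
    )
    return scan


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, sd)
    out = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])[0]
    return out


def make_pressure_series(
    gamma_target: float,
    lz: float = 12.189,
    mean_pressure: float = 1.0,
    noise_sd: float = 50.0,
    ar1_phi: float = 0.3,
    n_frames: int = 50_000,
    dt: float = 2.0,
    seed: int = 0,
) -> PressureTensorSeries:
    """Pressure-tensor series whose expected slab surface tension is the target.

    The tangential components fluctuate around ``mean_pressure`` [bar] and
    the normal component around the offset that makes the standard slab
    formula yield ``gamma_target`` [mN/m] exactly in expectation.  Each
    component carries independent AR(1) noise.
    """
    if lz <= 0:
        raise ValueError("Lz must be positive")
    if not abs(ar1_phi) < 1:
        raise ValueError("|ar1_phi| must be < 1")
    rng = np.random.default_rng(seed)
    delta = gamma_target / (0.5 * lz * BAR_NM_TO_MN_PER_M)
    time = np.arange(n_frames) * dt
    pxx = mean_pressure + _ar1(rng, n_frames, noise_sd, ar1_phi)
    pyy = mean_pressure + _ar1(rng, n_frames, noise_sd, ar1_phi)
    pzz = mean_pressure + delta + _ar1(rng, n_frames, noise_sd, ar1_phi)
    series = PressureTensorSeries(time, pxx, pyy, pzz, lz)
    series.meta["spec"] = FixtureSpec(
        seed=seed,
        sizes=(n_frames, dt),
        targets=(float(gamma_target),),
        noise=(float(noise_sd), float(ar1_phi)),
    )
    return series


def make_perturbation_run(
    eta_target: float,
    amplitude: float,
    rho: float = 900.0,
    lz: float = 16.382,
    n_atoms: int = 1000,
    thermal_sd: float = 0.45,
    n_frames: int = 1500,
    dt: float = 1.0,
    seed: int = 0,
) -> PerturbationRun:
    """Perturbation-run snapshots whose shear-viscosity estimate is the target.

    The steady-state velocity field is v_x(z) = V* cos(2 pi z / Lz) with
    V* = A rho (Lz/2 pi)^2 / eta*, plus i.i.d. Gaussian thermal noise.
    Atom z positions sit on a uniform grid over [0, Lz), which makes the
    cosine quadrature exact: at zero thermal noise the estimator returns
    eta* to machine precision.
    """
    if min(eta_target, amplitude, rho, lz) <= 0 or thermal_sd < 0:
        raise ValueError("all physical inputs must be positive")
    rng = np.random.default_rng(seed)
    v_star = (
        amplitude * rho * (lz / (2.0 * np.pi)) ** 2 * KGM3_NM2_PER_PS_TO_MPAS
    ) / eta_target
    z = (np.arange(n_atoms) + 0.5) * lz / n_atoms
    masses = np.full(n_atoms, 14.0)
    time = np.arange(n_frames) * dt
    v_field = v_star * np.cos(2.0 * np.pi * z / lz)
    v_x = np.tile(v_field, (n_frames, 1))
    if thermal_sd > 0:
        v_x = v_x + rng.normal(0.0, thermal_sd, size=(n_frames, n_atoms))
    run = PerturbationRun(
        masses=masses,
        z=np.tile(z, (n_frames, 1)),
        v_x=v_x,
        time=time,
        amplitude=amplitude,
        rho=rho,
        lz=lz,
    )
    run.meta["spec"] = FixtureSpec(
        seed=seed,
        sizes=(n_frames, n_atoms, dt),
        targets=(float(eta_target), float(v_star)),
        noise=(float(thermal_sd),),
    )
    return run


def make_energy_components(
    hvap_target: float,
    temperature: float = 382.0,
    n_molecules: int = 219,
    seed: int = 0,
) -> tuple[EnergyComponents, EnergyComponents]:
    """(gas, liquid) energy decompositions with exact dHvap round trip.

    The gas-phase terms and the liquid intramolecular terms are drawn at
    random; the intermolecular liquid energy absorbs whatever is needed so
    that dHvap = E(g) - E(l)/N + RT equals the target exactly.
    """
    rng = np.random.default_rng(seed)
    gas = EnergyComponents(
        e_dih=float(rng.uniform(5.0, 20.0)),
        e_intra_nb=float(rng.uniform(-10.0, 10.0)),
        e_inter=0.0,
        temperature=temperature,
        n_molecules=1,
    )
    e_liq_per_mol = gas.total + R_GAS * temperature - hvap_target
    e_dih_l = float(rng.uniform(5.0, 20.0)) * n_molecules
    e_intra_l = float(rng.uniform(-10.0, 10.0)) * n_molecules
    e_inter_l = e_liq_per_mol * n_molecules - e_dih_l - e_intra_l
    liquid = EnergyComponents(
        e_dih=e_dih_l,
        e_intra_nb=e_intra_l,
        e_inter=e_inter_l,
        temperature=temperature,
        n_molecules=n_molecules,
    )
    return gas, liquid
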