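"""Dihedral scan generation and Fourier-coefficient fitting.

The rotational profile of a bond is scanned in fixed steps (10 degrees by
default) by rigidly rotating one side of the molecule.  The target torsion
potential is then obtained by least squares: with the QM relative energies
dE_QM(a) and the force-field residual (all intramolecular terms except the
torsion type being fitted), the model

    residual(a) + sum_inst E_OPLS(V; phi_inst(a)) + c  ~  dE_QM(a)

is linear in V1..V4 and the constant offset c, so the coefficients and
their covariance come from an ordinary linear least-squares solve.  All
torsion instances of the fitted type sharing the driven central bond enter
the design (a methyl rotor contributes three symmetric instances, for
example), and the coefficients are per *type*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield_core import (
    Conformation,
    MolecularTopology,
    _dihedral_angles_rad,
    fourier_energy,
    intramolecular_energy,
    measure_dihedral,
    moving_side,
    rotate_dihedral,
)
from .units import HARTREE_TO_KJMOL

__all__ = [
    "TorsionScan",
    "FourierFit",
    "ConditioningError",
    "build_scan",
    "fit_fourier",
    "profile_rmse",
    "profile_report",
    "read_scan_csv",
    "write_scan_csv",
]

#: Energy above which a scan point is flagged as a steric clash.
CLASH_ENERGY = 1.0e7

_HARMONIC_NAMES = ("V1", "V2", "V3", "V4", "offset")


class ConditioningError(Exception):
    """The fit design matrix is rank deficient."""


@dataclass
class TorsionScan:
    """One torsion scan: angles [deg], QM and residual FF energies [kJ/mol].

    ``instance_angles`` (n_angles x n_instances) holds the torsion angle of
    every instance of the fitted type at each scan point; for a scan built
    outside :func:`build_scan` it defaults to the scan angle itself.
    """

    angles: np.ndarray
    residual_ff_energy: np.ndarray
    qm_energy: np.ndarray | None = None
    dihedral_id: tuple | None = None
    instance_angles: np.ndarray | None = None
    clash: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.residual_ff_energy = np.asarray(self.residual_ff_energy, dtype=float)
        if self.qm_energy is not None:
            self.qm_energy = np.asarray(self.qm_energy, dtype=float)
            if self.qm_energy.shape != self.angles.shape:
                raise ValueError("qm_energy length mismatch")
            if not np.all(np.isfinite(self.qm_energy)):
                raise ValueError("qm energies must be finite")
        if self.residual_ff_energy.shape != self.angles.shape:
            raise ValueError("residual energy length mismatch")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("scan angles must be strictly increasing")
        ok = self.clash is None or not np.any(self.clash)
        if ok and not np.all(np.isfinite(self.residual_ff_energy)):
            raise ValueError("residual energies must be finite")

    @property
    def n_points(self) -> int:
        return len(self.angles)


@dataclass
class FourierFit:
    """Fitted OPLS coefficients with offset, per-angle residuals and rmse."""

    v1: float
    v2: float
    v3: float
    v4: float
    offset: float
    rmse: float
    residuals: np.ndarray
    standard_errors: np.ndarray | None = None
    covariance: np.ndarray | None = None

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.v1, self.v2, self.v3, self.v4)


def _fitted_instances(top: MolecularTopology, dihedral_id: tuple[int, int, int, int]):
    """Torsion terms of the driven torsion's type sharing its central bond."""
    i, j, k, l = dihedral_id
    driven = None
    for d in top.dihedrals:
        if {d.i, d.j, d.k, d.l} == {i, j, k, l} and {d.j, d.k} == {j, k}:
            driven = d
            break
    if driven is None:
        raise ValueError("dihedral_id not present in topology")

    def type_tuple(d):
        t = tuple(top.atoms[a].type.name for a in (d.i, d.j, d.k, d.l))
        return min(t, t[::-1])

    want = type_tuple(driven)
    central = {j, k}
    return [
        d for d in top.dihedrals
        if {d.j, d.k} == central and type_tuple(d) == want
    ]


def build_scan(
    top: MolecularTopology,
    conf: Conformation,
    dihedral_id: tuple[int, int, int, int],
    step: float = 10.0,
) -> TorsionScan:
    """Scan the torsion in ``step``-degree increments over [0, 360).

    The side of the molecule containing atom k is rigidly rotated while the
    rest stays fixed.  The residual column holds the full intramolecular
    energy minus the contribution of every instance of the fitted torsion
    type on the driven bond; the QM column is left empty for the caller.
    Points whose energy overflows (steric clash) are flagged, not NaN.
    """
    i, j, k, l = dihedral_id
    instances = _fitted_instances(top, dihedral_id)
    inst_idx = np.array([(d.i, d.j, d.k, d.l) for d in instances], dtype=int)
    inst_v = [d.coefficients for d in instances]
    moving = moving_side(top, j, k)
    phi0 = measure_dihedral(conf, i, j, k, l)
    angles = np.arange(0.0, 360.0, float(step))
    residual = np.empty_like(angles)
    inst_angles = np.empty((len(angles), len(instances)))
    clash = np.zeros(len(angles), dtype=bool)
    for n, alpha in enumerate(angles):
        rotated = rotate_dihedral(conf, j, k, moving, alpha - phi0)
        total = intramolecular_energy(top, rotated).total
        phis = np.degrees(_dihedral_angles_rad(rotated.coordinates, inst_idx))
        inst_angles[n] = phis
        own = sum(fourier_energy(v, p) for v, p in zip(inst_v, phis))
        res = total - own
        if not np.isfinite(res) or abs(res) > CLASH_ENERGY:
            clash[n] = True
            res = np.nan
        residual[n] = res
    return TorsionScan(
        angles=angles,
        residual_ff_energy=residual,
        dihedral_id=tuple(dihedral_id),
        instance_angles=inst_angles,
        clash=clash,
        meta={"step": float(step), "n_instances": len(instances)},
    )


def _design_matrix(scan: TorsionScan, freeze_v4: bool, fit_offset: bool):
    phi = scan.instance_angles
    if phi is None:
        phi = scan.angles[:, None]
    phi = np.radians(phi)
    cols = [
        0.5 * np.sum(1.0 + np.cos(phi), axis=1),
        0.5 * np.sum(1.0 - np.cos(2.0 * phi), axis=1),
        0.5 * np.sum(1.0 + np.cos(3.0 * phi), axis=1),
        0.5 * np.sum(1.0 - np.cos(4.0 * phi), axis=1),
    ]
    names = list(_HARMONIC_NAMES[:4])
    if freeze_v4:
        cols.pop(3)
        names.pop(3)
    if fit_offset:
        cols.append(np.ones(scan.n_points))
        names.append("offset")
    return np.column_stack(cols), names


def fit_fourier(
    scan: TorsionScan,
    freeze_v4: bool = False,
    fit_offset: bool = True,
    loss: str = "l2",
) -> FourierFit:
    """Fit V1..V4 (and offset c) so FF relative energies match the QM scan.

    Least squares (``loss='l2'``, default) with coefficient standard errors
    from the least-squares covariance; ``loss='l1'`` solves the least
    absolute deviations problem by linear programming (no standard errors).
    """
    if scan.qm_energy is None:
        raise ValueError("scan has no QM energies to fit against")
    mask = ~scan.clash if scan.clash is not None else np.ones(scan.n_points, bool)
    x, names = _design_matrix(scan, freeze_v4, fit_offset)
    x = x[mask]
    y = (scan.qm_energy - scan.residual_ff_energy)[mask]
    n, p = x.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} scan points, got {n}")

    sv = np.linalg.svd(x, compute_uv=False)
    if sv[-1] / sv[0] < 1e-10:
        bad = _name_unresolvable(x, names)
        raise ConditioningError(
            f"scan angles cannot resolve harmonic(s): {', '.join(bad)}"
        )

    if loss == "l1":
        beta = _lad_solve(x, y)
        cov = se = None
    elif loss == "l2":
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = x @ beta - y
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = np.sqrt(np.diag(cov))
    else:
        raise ValueError("loss must be 'l2' or 'l1'")

    coeffs = dict(zip(names, beta))
    se_map = dict(zip(names, se)) if se is not None else {}
    v = [coeffs.get(f"V{i}", 0.0) for i in (1, 2, 3, 4)]
    offset = coeffs.get("offset", 0.0)
    residuals = x @ beta - y
    rmse = float(np.sqrt(np.mean(residuals**2)))
    se_full = (
        np.array([se_map.get(nm, 0.0) for nm in _HARMONIC_NAMES])
        if se is not None
        else None
    )
    return FourierFit(
        *[float(c) for c in v],
        offset=float(offset),
        rmse=rmse,
        residuals=residuals,
        standard_errors=se_full,
        covariance=cov,
    )


def _name_unresolvable(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for c in range(x.shape[1]):
        others = np.delete(x, c, axis=1)
        beta, *_ = np.linalg.lstsq(others, x[:, c], rcond=None)
        resid = x[:, c] - others @ beta
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(x[:, c]), 1.0):
            bad.append(names[c])
    return bad or ["<unknown>"]


def _lad_solve(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least absolute deviations via linear programming."""
    from scipy.optimize import linprog

    n, p = x.shape
    # variables: beta (free, split +/-), slack t >= |r|
    c = np.concatenate([np.zeros(2 * p), np.ones(n)])
    a_ub = np.block(
        [[x, -x, -np.eye(n)], [-x, x, -np.eye(n)]]
    )
    b_ub = np.concatenate([y, -y])
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, method="highs")
    if not res.success:
        raise RuntimeError(f"L1 fit failed: {res.message}")
    z = res.x
    return z[:p] - z[p : 2 * p]


def _predict(fit: FourierFit, scan: TorsionScan) -> np.ndarray:
    phi = scan.instance_angles
    if phi is None:
        phi = scan.angles[:, None]
    own = np.sum(
        [fourier_energy(fit.coefficients, phi[:, m]) for m in range(phi.shape[1])],
        axis=0,
    )
    return scan.residual_ff_energy + own + fit.offset


def profile_rmse(fit: FourierFit, scan: TorsionScan) -> float:
    """RMS difference between the fitted FF profile and the QM profile."""
    if scan.qm_energy is None:
        raise ValueError("scan has no QM energies")
    mask = ~scan.clash if scan.clash is not None else np.ones(scan.n_points, bool)
    diff = (_predict(fit, scan) - scan.qm_energy)[mask]
    return float(np.sqrt(np.mean(diff**2)))


def profile_report(
    fit: FourierFit,
    scan: TorsionScan,
    original_coefficients=None,
) -> pd.DataFrame:
    """Per-angle comparison table, each profile re-zeroed to its minimum.

    Columns: scan angle, QM relative energy, fitted FF relative energy and,
    if original coefficients are given, the unfit FF relative energy.
    """
    data = {"angle_deg": scan.angles}
    if scan.qm_energy is not None:
        data["d_e_qm"] = scan.qm_energy - np.nanmin(scan.qm_energy)
    fitted = _predict(fit, scan)
    data["d_e_ff_fitted"] = fitted - np.nanmin(fitted)
    if original_coefficients is not None:
        phi = scan.instance_angles
        if phi is None:
            phi = scan.angles[:, None]
        own = np.sum(
            [fourier_energy(original_coefficients, phi[:, m]) for m in range(phi.shape[1])],
            axis=0,
        )
        orig = scan.residual_ff_energy + own
        data["d_e_ff_original"] = orig - np.nanmin(orig)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Scan exchange format
# ---------------------------------------------------------------------------


def write_scan_csv(scan: TorsionScan, path) -> None:
    df = pd.DataFrame({"angle_deg": scan.angles})
    if scan.qm_energy is not None:
        df["qm_energy_kjmol"] = scan.qm_energy
    df["residual_kjmol"] = scan.residual_ff_energy
    df.to_csv(path, index=False)


def read_scan_csv(path, qm_in_hartree: bool = False) -> TorsionScan:
    """Read ``angle_deg,qm_energy_kjmol[,residual_kjmol]`` (or hartree QM)."""
    df = pd.read_csv(path)
    qm_col = next((c for c in df.columns if c.startswith("qm_energy")), None)
    qm = None
    if qm_col is not None:
        qm = df[qm_col].to_numpy(dtype=float)
        if qm_in_hartree or qm_col.endswith("hartree"):
            qm = qm * HARTREE_TO_KJMOL
    residual = (
        df["residual_kjmol"].to_numpy(dtype=float)
        if "residual_kjmol" in df.columns
        else np.zeros(len(df))
    )
    return TorsionScan(
        angles=df["angle_deg"].to_numpy(dtype=float),
        residual_ff_energy=residual,
        qm_energy=qm,
    )
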