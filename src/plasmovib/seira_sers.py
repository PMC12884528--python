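"""Surface-enhanced IR (SEIRA) and Raman (SERS) intensities and
enhancement statistics.

SEIRA follows the induced-dipole route: the adsorbed molecule's oscillating
density (point charges + compensating atomic dipoles of the surrogate)
generates a potential V^QM and field E^QM on the substrate atoms; solving
the substrate response with these as the source yields charges/dipoles
whose reduction d̃ = Σ_p (q_p r_p + μ_p) is the dipole induced on the
nanostructure. The observable IR intensity of mode i is built from the
geometric derivative of the *total* dipole d + d̃, taken by a three-point
central difference along the cartesian normal-mode vector with a 0.001 Bohr
step, with the substrate solved at the normal-mode frequency ω_i.

SERS is treated with the classical dressed-tensor scheme: the effective
Raman tensor of mode i is a_i^eff = Λᵀ(ω_inc)·(∂α/∂Q_i)·Λ(ω_inc), with the
local-field tensor Λ evaluated at the molecular centroid, the incident
frequency typically set at the substrate PRF, and a 0.10 eV phenomenological
lifetime folded into the substrate damping.

Per-mode enhancement factors, their intensity-weighted average (AEF), the
maximum (MEF) and the index of the maximizing mode (i-MEF) are collected in
an EnhancementReport:

    EF_i = I_i / I_i^vac,  AEF = Σ_i I_i / Σ_l I_l^vac,  MEF = max_i EF_i.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .kernels import fields_from_sources
from .materials import with_extra_damping
from .molecule import (
    IR_KM_MOL,
    MolecularSurrogate,
    gas_ir_intensities,
    gas_raman_activities,
    raman_invariants,
)
from .response import (
    ExternalSource,
    ResponseSolution,
    SubstrateModel,
    scattered_field_at,
    solve,
    uniform_field_source,
)
from .units import BOHR_ANGSTROM, angstrom_to_bohr, cm_to_ev

__all__ = [
    "EnhancementReport",
    "InducedDipole",
    "molecular_sources",
    "induced_external_dipole",
    "local_field_tensor",
    "dressed_dipole_derivative",
    "dressed_raman_tensor",
    "seira_intensities",
    "sers_intensities",
    "enhancement_report",
    "average_reports",
    "DIFF_STEP_BOHR",
]

DIFF_STEP_BOHR = 0.001      # three-point central differentiation step
SERS_LIFETIME_EV = 0.10     # phenomenological broadening of the dressing


@dataclass
class EnhancementReport:
    """Per-mode enhanced intensities and the Eq.-style EF/AEF/MEF summary.

    Modes whose vacuum intensity is zero are excluded from EF and MEF but
    kept in the AEF sums.
    """

    freqs_cm: np.ndarray
    intensities: np.ndarray
    vac_intensities: np.ndarray
    ef: np.ndarray          # NaN where vac intensity is zero
    aef: float
    mef: float
    i_mef: int              # index into freqs_cm of the maximizing mode


@dataclass
class InducedDipole:
    """Substrate dipole d̃ induced by the molecular density (au)."""

    value: np.ndarray
    source_solution: ResponseSolution


def molecular_sources(mol: MolecularSurrogate, model: SubstrateModel) -> ExternalSource:
    """Potential V^QM and field E^QM of the surrogate density at the
    substrate atoms, using the substrate's own Gaussian regularization
    (molecular multipoles enter as points)."""
    sub_pos = model.kernels.positions_au
    mol_pos = angstrom_to_bohr(mol.positions)
    # validity: sources must stay outside the regularization cores
    tree = cKDTree(model.structure.positions)
    dmin = float(tree.query(mol.positions)[0].min())
    if dmin < 1.0:
        raise ValueError(
            f"molecule–substrate distance {dmin:.2f} Å is below the "
            "regularization validity range"
        )
    # pair widths broadcast over (target, source); the molecule enters as
    # point multipoles, so each pair's width is the substrate atom's width
    V, E = fields_from_sources(
        mol_pos,
        mol.charges.astype(complex),
        None if mol.dipoles is None else mol.dipoles.astype(complex),
        sub_pos,
        model.kernels.widths[:, None],
    )
    return ExternalSource(V, E, descriptor="molecular")


def induced_external_dipole(
    mol: MolecularSurrogate, model: SubstrateModel, omega_ev: float, **kw
) -> InducedDipole:
    """Solve the substrate response driven by the molecular density at ω and
    reduce it to the induced dipole d̃ = Σ_p (q_p r_p + μ_p)."""
    if model.n == 0:
        zero = ResponseSolution(omega_ev, np.zeros(0, complex), None,
                                np.zeros(3, complex), 0.0,
                                np.zeros((0, 3)), np.zeros(0))
        return InducedDipole(np.zeros(3, complex), zero)
    src = molecular_sources(mol, model)
    sol = solve(model, omega_ev, src, **kw)
    return InducedDipole(sol.induced_dipole, sol)


def probe_projected_dipole(solution: ResponseSolution) -> np.ndarray:
    """d̃ recovered by projecting onto three orthogonal uniform probe
    fields: −d̃·ê = Σ_p [q_p V^ext(r_p) − μ_p·E^ext(r_p)] with V^ext = −ê·r.

    Algebraically identical to Σ(q_p r_p + μ_p); kept as an independent
    reduction for the structural identity test.
    """
    d = np.zeros(3, dtype=complex)
    for b, e in enumerate(np.eye(3)):
        V = -(solution.positions_au @ e)
        rhs = np.sum(solution.charges * V)
        if solution.dipoles is not None:
            rhs = rhs - np.sum(solution.dipoles @ e)
        d[b] = -rhs
    return d


def local_field_tensor(model: SubstrateModel, point_angstrom, omega_ev: float,
                       **kw) -> np.ndarray:
    """Λ(ω) = I + scattered-field tensor at a point per unit uniform field.

    Columns are total (applied + scattered) fields at the point for unit
    uniform fields along x, y, z.
    """
    point = np.atleast_2d(np.asarray(point_angstrom, dtype=float))
    lam = np.eye(3, dtype=complex)
    if model is None or model.n == 0:
        return lam
    for b, axis in enumerate(np.eye(3)):
        sol = solve(model, omega_ev, uniform_field_source(model.structure, axis), **kw)
        _, E = scattered_field_at(sol, point)
        lam[:, b] += E[0]
    return lam


def dressed_dipole_derivative(ddq: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """SEIRA local-field dressing of a dipole derivative: Λᵀ·(∂d/∂Q)."""
    return lam.T @ np.asarray(ddq, dtype=complex)


def dressed_raman_tensor(alpha_deriv: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """SERS dressed Raman tensor a^eff = Λᵀ·(∂α/∂Q)·Λ."""
    return lam.T @ np.asarray(alpha_deriv, dtype=complex) @ lam


def _displaced(mol: MolecularSurrogate, direction: np.ndarray, eps_bohr: float
               ) -> MolecularSurrogate:
    """Surrogate displaced by eps·û along a cartesian direction (N,3),
    carrying the compensating atomic dipoles (APT − q·I)·ΔR so that the
    molecular dipole stays exactly linear with APT slope."""
    dr_bohr = eps_bohr * direction
    pos = mol.positions + dr_bohr * BOHR_ANGSTROM
    comp = np.einsum("nab,nb->na", mol.apt, dr_bohr) - mol.charges[:, None] * dr_bohr
    dip = comp if mol.dipoles is None else mol.dipoles + comp
    return replace(mol, positions=pos, dipoles=dip)


def seira_intensities(
    mol: MolecularSurrogate,
    model: Optional[SubstrateModel],
    step_bohr: float = DIFF_STEP_BOHR,
    **kw,
):
    """SEIRA intensities and enhancement report.

    For each normal mode the total dipole d + d̃ is differentiated by the
    three-point central scheme along the cartesian mode vector (step
    ``step_bohr``, default 0.001 Bohr; halve it to mirror the stability
    check), with the substrate solved at the mode frequency. Without a
    substrate this reduces exactly to the gas-phase intensities.

    Returns (intensities km/mol, EnhancementReport).
    """
    vac = gas_ir_intensities(mol)
    if model is None or model.n == 0:
        report = enhancement_report(mol.freqs_cm, vac.copy(), vac)
        return vac.copy(), report
    Lc = mol.cartesian_modes()                    # (nm, N, 3)
    intensities = np.empty(mol.n_modes)
    for i in range(mol.n_modes):
        norm = np.linalg.norm(Lc[i])
        u = Lc[i] / norm
        omega_i = cm_to_ev(mol.freqs_cm[i])
        dtot = []
        for sgn in (+1.0, -1.0):
            disp = _displaced(mol, u, sgn * step_bohr)
            dt = disp.dipole().astype(complex)
            dt += induced_external_dipole(disp, model, omega_i, **kw).value
            dtot.append(dt)
        ddq = (dtot[0] - dtot[1]) / (2.0 * step_bohr) * norm   # e·amu^(−1/2)
        intensities[i] = IR_KM_MOL * float(np.sum(np.abs(ddq) ** 2))
    report = enhancement_report(mol.freqs_cm, intensities, vac)
    return intensities, report


def sers_intensities(
    mol: MolecularSurrogate,
    model: Optional[SubstrateModel],
    omega_inc_ev: float,
    lifetime_ev: float = SERS_LIFETIME_EV,
    **kw,
):
    """Classical dressed-tensor SERS activities and enhancement report.

    The local-field tensor Λ(ω_inc) is evaluated at the molecular centroid
    with an extra phenomenological broadening (default 0.10 eV) in the
    substrate Drude damping; every mode shares the single incident-frequency
    dressing (no Stokes shift). Without a substrate this reduces to the
    gas-phase activities.
    """
    vac = gas_raman_activities(mol)
    if model is None or model.n == 0:
        report = enhancement_report(mol.freqs_cm, vac.copy(), vac)
        return vac.copy(), report
    damped = replace(
        model,
        params=with_extra_damping(model.params, lifetime_ev),
        kbar=model.kbar,
        kernels=model.kernels,
    )
    centroid = mol.positions.mean(axis=0)
    lam = local_field_tensor(damped, centroid, omega_inc_ev, **kw)
    eff = np.array([dressed_raman_tensor(a, lam) for a in mol.alpha_deriv])
    a2, g2 = raman_invariants(eff)
    intensities = 45.0 * a2 + 7.0 * g2
    report = enhancement_report(mol.freqs_cm, intensities, vac)
    return intensities, report


def enhancement_report(
    freqs_cm: Sequence[float],
    intensities: np.ndarray,
    vac_intensities: np.ndarray,
) -> EnhancementReport:
    """Assemble EF/AEF/MEF/i-MEF from enhanced and vacuum intensities.

    EF_i = I_i/I_i^vac where I_i^vac > 0 (NaN otherwise, excluded from
    MEF); AEF = ΣI/ΣI^vac over all modes; ties for the maximum EF break
    toward the lowest frequency.
    """
    freqs = np.asarray(freqs_cm, dtype=float)
    I = np.asarray(intensities, dtype=float)
    Iv = np.asarray(vac_intensities, dtype=float)
    if I.shape != Iv.shape:
        raise ValueError("intensity lists must have equal length")
    if np.any(Iv < 0):
        raise ValueError("vacuum intensities must be non-negative")
    tot_vac = Iv.sum()
    if tot_vac == 0:
        raise ZeroDivisionError("all-zero vacuum spectrum: AEF undefined")
    ef = np.full_like(I, np.nan)
    ok = Iv > 0
    ef[ok] = I[ok] / Iv[ok]
    aef = float(I.sum() / tot_vac)
    mef = float(np.nanmax(ef))
    maximizers = np.flatnonzero(ok & (ef == mef))
    i_mef = int(maximizers[np.argmin(freqs[maximizers])])
    return EnhancementReport(freqs, I, Iv, ef, aef, mef, i_mef)


def average_reports(reports: Sequence[EnhancementReport]) -> EnhancementReport:
    """Configuration-averaged report: arithmetic mean of the per-mode
    intensities over configurations sharing the same mode list; EF/AEF/MEF
    recomputed from the averages."""
    if not reports:
        raise ValueError("no reports to average")
    f0 = reports[0].freqs_cm
    for r in reports[1:]:
        if len(r.freqs_cm) != len(f0) or np.max(np.abs(r.freqs_cm - f0)) > 1e-9:
            raise ValueError("reports have mismatched mode lists")
    I = np.mean([r.intensities for r in reports], axis=0)
    Iv = np.mean([r.vac_intensities for r in reports], axis=0)
    return enhancement_report(f0, I, Iv)
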