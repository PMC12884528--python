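"""Conduction matrix and regularized electrostatic interaction kernels.

Two ingredients of the frequency-domain response systems live here:

* the nearest-neighbor Drude conduction matrix K̄, with the Fermi-like
  tunneling damping f(r) that switches conduction off beyond the
  equilibrium bond distance, and
* the Gaussian-regularized Coulomb kernels T^qq, T^qμ, T^μq, T^μμ between
  smeared atomic charges and point dipoles.

Regularization: each atom carries a Gaussian charge of width w_i, so two
atoms interact through erf(r/R_ij)/r with R_ij = √(w_i² + w_j²). This is
finite at r → 0 and reduces to the bare Coulomb/dipole kernels in the far
field.

Sign convention (fixed once, used everywhere): kernels produce potentials
and fields of unit *positive* sources, time dependence e^(−iωt).
Writing g0 = erf(r/R)/r, Δ = r_i − r_j,

    potential at i from charge q_j :  g0 · q_j                    (T^qq)
    potential at i from dipole μ_j :  −g1 Δ·μ_j                   (T^qμ)
    −(field at i from charge q_j)  :  +g1 Δ  q_j                  (T^μq)
    −(field at i from dipole μ_j)  :  −(g1 I + g2 ΔΔᵀ) μ_j        (T^μμ)

with g1 = (1/r) dg0/dr and g2 = (1/r) dg1/dr, so T^μq = (T^qμ)ᵀ and the
full 4N×4N interaction matrix is symmetric. The dipole rows carry the
*negative* field because the block system moves them to the left-hand side
(an isolated atom then satisfies μ = α_IB·E exactly).

Self terms: T^qq keeps the Gaussian self-interaction 2/(√π·√2·w_i) (the
charge-hardness analogue); the dipole blocks exclude i = j since the atomic
polarizability already accounts for the on-site response.

All kernel quantities are in atomic units; structures come in with Å
positions and are converted on entry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .structures import NanoStructure
from .units import angstrom_to_bohr

__all__ = [
    "fermi_damping",
    "build_conduction_matrix",
    "build_interaction_kernels",
    "ConductionMatrix",
    "InteractionKernels",
    "coulomb_g",
    "DEFAULT_WIDTH_SCALE",
]

# Gaussian width as a fraction of the nearest-neighbor distance; a pure
# regularization choice, exposed in the config surface.
DEFAULT_WIDTH_SCALE = 0.4

_SQRT_PI = math.sqrt(math.pi)


def fermi_damping(r, r0, steepness, scale):
    """Fermi-like tunneling profile f(r) = 1/(1 + exp[−d(r/(s·r⁰) − 1)]).

    Strictly increasing in r, f(s·r⁰) = 1/2; the conduction factor is
    1 − f(r), so charge flow dies off smoothly beyond ~s·r⁰. Any consistent
    length unit may be used for r and r0.
    """
    r = np.asarray(r, dtype=float)
    x = -steepness * (r / (scale * r0) - 1.0)
    # clip to avoid overflow in exp; f saturates anyway
    return 1.0 / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


@dataclass
class ConductionMatrix:
    """Drude conduction matrix K̄ (au), sparse, column sums exactly zero."""

    kbar: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.kbar.shape[0]

    def toarray(self) -> np.ndarray:
        return self.kbar.toarray()


def build_conduction_matrix(
    structure: NanoStructure,
    params,
    eff_area_per_atom: Optional[np.ndarray] = None,
) -> ConductionMatrix:
    """Assemble K̄ from the neighbor graph.

    K_ij = [1 − f(r_ij)]·√(𝒜_i 𝒜_j)/r_ij on neighbor pairs (au), zero
    elsewhere and on the diagonal; K̄ = K − diag(row sums). The geometric
    mean of the effective areas keeps K symmetric for heterogeneous atoms
    and reduces to 𝒜/r_ij for a uniform material.
    """
    n = structure.n_atoms
    if len(structure.pairs) == 0:
        warnings.warn(
            "empty neighbor graph: isolated atoms carry no conduction",
            stacklevel=2,
        )
        return ConductionMatrix(sp.csr_matrix((n, n)))
    area = (
        np.full(n, params.eff_area)
        if eff_area_per_atom is None
        else np.asarray(eff_area_per_atom, dtype=float)
    )
    i, j = structure.pairs[:, 0], structure.pairs[:, 1]
    r_au = angstrom_to_bohr(structure.pair_distances)
    f = fermi_damping(
        structure.pair_distances, params.r0, params.tunnel_steepness, params.tunnel_scale
    )
    k_ij = (1.0 - f) * np.sqrt(area[i] * area[j]) / r_au

    rows = np.concatenate([i, j])
    cols = np.concatenate([j, i])
    vals = np.concatenate([k_ij, k_ij])
    K = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    row_sums = np.asarray(K.sum(axis=1)).ravel()
    kbar = (K - sp.diags(row_sums)).tocsr()
    return ConductionMatrix(kbar)


def coulomb_g(r, R):
    """Scalar kernels (g0, g1, g2) of the erf-regularized Coulomb potential.

    g0 = erf(r/R)/r, g1 = (1/r) dg0/dr, g2 = (1/r) dg1/dr, with the finite
    r → 0 limits g0 → 2/(√π R), g1 → −4/(3√π R³), g2 → +8/(5·... series)
    handled explicitly. Shapes broadcast.
    """
    from scipy.special import erf

    r = np.asarray(r, dtype=float)
    R = np.broadcast_to(np.asarray(R, dtype=float), r.shape)
    small = r < 1e-8 * R
    rs = np.where(small, 1.0, r)  # safe divisor
    u = rs / R
    e = np.exp(-(u**2))
    erf_u = erf(u)
    g0 = erf_u / rs
    g1 = 2.0 / (_SQRT_PI * R) * e / rs**2 - erf_u / rs**3
    g2 = 3.0 * erf_u / rs**5 - 2.0 / (_SQRT_PI * R) * e * (3.0 / rs**4 + 2.0 / (R**2 * rs**2))
    g0 = np.where(small, 2.0 / (_SQRT_PI * R), g0)
    g1 = np.where(small, -4.0 / (3.0 * _SQRT_PI * R**3), g1)
    g2 = np.where(small, 8.0 / (5.0 * _SQRT_PI * R**5), g2)
    return g0, g1, g2


@dataclass
class InteractionKernels:
    """Regularized Coulomb kernels for one structure.

    Exposes matrix-vector products `apply_qq`, `apply_qmu`, `apply_muq`,
    `apply_mumu`; below `dense_threshold` atoms the N×N (and 3N-sized)
    matrices are assembled once and reused, above it products are computed
    on the fly in row chunks without storing any N² array.
    """

    positions_au: np.ndarray          # (N, 3)
    widths: np.ndarray                # (N,) Gaussian widths, au
    dense_threshold: int = 4000
    chunk: int = 512
    _Tqq: Optional[np.ndarray] = field(default=None, repr=False)
    _Tqmu: Optional[np.ndarray] = field(default=None, repr=False)
    _Tmumu: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.positions_au)

    @property
    def is_dense(self) -> bool:
        return self.n <= self.dense_threshold

    # -- dense assembly -----------------------------------------------------

    def _pair_geometry(self, idx):
        pos = self.positions_au
        delta = pos[idx, None, :] - pos[None, :, :]          # (m, N, 3)
        r = np.linalg.norm(delta, axis=-1)                   # (m, N)
        R = np.sqrt(self.widths[idx, None] ** 2 + self.widths[None, :] ** 2)
        return delta, r, R

    def tqq(self) -> np.ndarray:
        """Dense T^qq (N×N), including the Gaussian self-interaction."""
        if self._Tqq is None:
            delta, r, R = self._pair_geometry(np.arange(self.n))
            g0, _, _ = coulomb_g(r, R)
            self._Tqq = g0
        return self._Tqq

    def tqmu(self) -> np.ndarray:
        """Dense T^qμ (N×3N); columns grouped per atom (j,β)."""
        if self._Tqmu is None:
            delta, r, R = self._pair_geometry(np.arange(self.n))
            _, g1, _ = coulomb_g(r, R)
            blk = -g1[:, :, None] * delta                     # (N, N, 3)
            blk[np.arange(self.n), np.arange(self.n)] = 0.0
            self._Tqmu = blk.reshape(self.n, 3 * self.n)
        return self._Tqmu

    def tmuq(self) -> np.ndarray:
        """Dense T^μq (3N×N) = (T^qμ)ᵀ."""
        return self.tqmu().T.copy()

    def tmumu(self) -> np.ndarray:
        """Dense T^μμ (3N×3N), self-blocks zero."""
        if self._Tmumu is None:
            delta, r, R = self._pair_geometry(np.arange(self.n))
            _, g1, g2 = coulomb_g(r, R)
            blk = -(
                g1[:, :, None, None] * np.eye(3)[None, None]
                + g2[:, :, None, None] * delta[:, :, :, None] * delta[:, :, None, :]
            )                                                 # (N, N, 3, 3)
            blk[np.arange(self.n), np.arange(self.n)] = 0.0
            self._Tmumu = blk.transpose(0, 2, 1, 3).reshape(3 * self.n, 3 * self.n)
        return self._Tmumu

    # -- matrix-vector products --------------------------------------------

    def apply_qq(self, x: np.ndarray) -> np.ndarray:
        if self.is_dense:
            return self.tqq() @ x
        out = np.zeros(self.n, dtype=np.result_type(x, float))
        for s in range(0, self.n, self.chunk):
            idx = np.arange(s, min(s + self.chunk, self.n))
            _, r, R = self._pair_geometry(idx)
            g0, _, _ = coulomb_g(r, R)
            out[idx] = g0 @ x
        return out

    def apply_qmu(self, m: np.ndarray) -> np.ndarray:
        """m: (3N,) dipoles flattened per atom → potentials (N,)."""
        mv = m.reshape(self.n, 3)
        if self.is_dense:
            return self.tqmu() @ m
        out = np.zeros(self.n, dtype=np.result_type(m, float))
        for s in range(0, self.n, self.chunk):
            idx = np.arange(s, min(s + self.chunk, self.n))
            delta, r, R = self._pair_geometry(idx)
            _, g1, _ = coulomb_g(r, R)
            w = -g1[:, :, None] * delta
            w[np.arange(len(idx)), idx] = 0.0
            out[idx] = np.einsum("mjb,jb->m", w, mv)
        return out

    def apply_muq(self, x: np.ndarray) -> np.ndarray:
        """x: (N,) charges → negative fields flattened (3N,)."""
        if self.is_dense:
            return self.tqmu().T @ x
        out = np.zeros((self.n, 3), dtype=np.result_type(x, float))
        for s in range(0, self.n, self.chunk):
            idx = np.arange(s, min(s + self.chunk, self.n))
            delta, r, R = self._pair_geometry(idx)
            _, g1, _ = coulomb_g(r, R)
            w = g1[:, :, None] * delta
            w[np.arange(len(idx)), idx] = 0.0
            out[idx] = np.einsum("mjb,j->mb", w, x)
        return out.ravel()

    def apply_mumu(self, m: np.ndarray) -> np.ndarray:
        mv = m.reshape(self.n, 3)
        if self.is_dense:
            return self.tmumu() @ m
        out = np.zeros((self.n, 3), dtype=np.result_type(m, float))
        for s in range(0, self.n, self.chunk):
            idx = np.arange(s, min(s + self.chunk, self.n))
            delta, r, R = self._pair_geometry(idx)
            _, g1, g2 = coulomb_g(r, R)
            dm = np.einsum("mjb,jb->mj", delta, mv)
            w = -(g1[:, :, None] * mv[None, :, :] + g2[:, :, None] * dm[:, :, None] * delta)
            w[np.arange(len(idx)), idx] = 0.0
            out[idx] = w.sum(axis=1)
        return out.ravel()


def build_interaction_kernels(
    structure: NanoStructure,
    width_scale: float = DEFAULT_WIDTH_SCALE,
    widths_au: Optional[np.ndarray] = None,
    dense_threshold: int = 4000,
) -> InteractionKernels:
    """Interaction kernels for a structure.

    Gaussian widths default to ``width_scale`` times the nearest-neighbor
    distance inferred from the neighbor graph (or the global minimum
    distance when no graph is present); an explicit per-atom `widths_au`
    overrides this.
    """
    pos_au = angstrom_to_bohr(structure.positions)
    n = structure.n_atoms
    if n >= 2:
        dmin = structure.min_distance()
        if not np.isfinite(dmin) or dmin <= 0:
            raise ValueError("coincident atoms: cannot regularize")
    if widths_au is None:
        if n >= 2:
            nn_au = angstrom_to_bohr(
                float(structure.pair_distances.min())
                if len(structure.pair_distances)
                else structure.min_distance()
            )
        else:
            nn_au = angstrom_to_bohr(2.885)
        widths_au = np.full(n, width_scale * nn_au)
    else:
        widths_au = np.asarray(widths_au, dtype=float)
    return InteractionKernels(pos_au, widths_au, dense_threshold=dense_threshold)


def fields_from_sources(
    src_pos_au: np.ndarray,
    charges: np.ndarray,
    dipoles: Optional[np.ndarray],
    targets_au: np.ndarray,
    R: np.ndarray,
):
    """Potential and field at target points from smeared charges/dipoles.

    ``R`` is the combined regularization width per source (pass the source
    atom widths to evaluate at external points, or √(w_i²+w_j²) for
    atom–atom terms). Returns (V, E) with shapes (P,) and (P, 3); complex
    sources are supported.
    """
    targets_au = np.atleast_2d(targets_au)
    delta = targets_au[:, None, :] - src_pos_au[None, :, :]   # (P, Ns, 3)
    r = np.linalg.norm(delta, axis=-1)
    g0, g1, g2 = coulomb_g(r, np.broadcast_to(R, r.shape))
    V = g0 @ charges
    E = -np.einsum("pj,pjb,j->pb", g1, delta, charges)
    if dipoles is not None:
        dm = np.einsum("pjb,jb->pj", delta, dipoles)
        V = V - np.einsum("pj,pj->p", g1, dm)
        # field of dipoles: E = (g1 I + g2 ΔΔᵀ)·μ  (the −T^μμ pairing)
        E = E + np.einsum("pj,jb->pb", g1, dipoles) + np.einsum("pj,pj,pjb->pb", g2, dm, delta)
    return V, E
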