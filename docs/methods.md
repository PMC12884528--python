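# Methods

## Substrate response model

The substrate is a set of N atoms at fixed positions. In the charge-only
model each atom carries a complex charge q_p(ω); in the charge+dipole model
an additional complex dipole μ_p(ω) represents the localized (interband)
polarizability of the d-shell. Both models are quasi-static: no
retardation, valid for structures small compared to the wavelength.

**Conduction.** Charge flows only between nearest neighbors (neighbor graph
cutoff 1.2× the equilibrium bond distance r⁰). The bond conductance is
Drude-like, K_ij = [1 − f(r_ij)]·√(𝒜_i𝒜_j)/r_ij, where the Fermi-type
profile f(r) = 1/(1 + exp[−d(r/(s·r⁰) − 1)]) smoothly switches conduction
off as bonds stretch, emulating the distance dependence of quantum
tunneling. The geometric mean of the effective areas keeps K symmetric for
heterogeneous atoms and reduces to 𝒜/r_ij for a uniform material. The
assembled matrix K̄ = K − diag(row sums) has zero column sums, which makes
substrate neutrality (Σ q_p = 0) an algebraic identity for any source —
this is tested, not merely assumed.

**Frequency dependence.** The diagonal shifts are
z_q(ω) = −ω(ωτ + i)/(2nτ) (Drude, with relaxation time τ and effective
density n) and z_μ(ω) = −1/α_IB(ω). The prefactor convention of z_q is
isolated in a single function so an alternative parametrization is a
one-line change. For graphene, n = E_F/(π a₀ ħ v_F) in atomic units —
strictly linear in the Fermi energy, consistent with E_F = ħ v_F √(π n_2D).
An effective mass m* (1 for metals) is absorbed into n.

**Electrostatics.** Atomic charges are Gaussian-smeared: two atoms of
widths w_i, w_j interact through erf(r/R)/r with R = √(w_i² + w_j²), finite
at r → 0 and Coulombic in the far field. Charge–dipole and dipole–dipole
kernels are the consistent first and second derivatives of the same
regularized potential, so the full interaction matrix is symmetric — the
property behind the electromagnetic-reciprocity test. The width defaults to
0.4× the nearest-neighbor distance; it is a regularization choice exposed
in the configuration surface. The charge–charge self-term (the hardness
analogue 2/(√π·√2 w)) is kept; dipole self-blocks are excluded so an
isolated atom satisfies μ = α_IB E exactly.

**Solvers.** Dense LU up to 4,000 atoms, GMRES (relative residual 1e-8,
warm-started along frequency scans) with matrix-free chunked kernel
products above. Dense and iterative paths are cross-checked to 1e-8 on
random clusters for both models. Observables: polarizability columns from
three axis solves; absorption cross-section σ(ω) = (4πω/c)·Im tr α/3; the
plasmon resonance frequency (PRF) is the global maximum of σ refined by a
three-point parabola (ties break to the lower frequency; refinement is
rejected if the vertex leaves the bracket, which matters for spiky
small-cluster spectra).

## Default material parameters

The published parametrizations of these models are not reproduced here;
the shipped defaults are qualitative placeholders with a documented
rationale, and any parameter set can be supplied via the YAML config
surface:

* **Gold**: ω_p = 9.07 eV (n = ω_p²/4π), ħ/τ = 0.0532 eV, r⁰ = 2.885 Å.
* **Graphene**: v_F = 0.457 au (1.0×10⁶ m/s), τ = 4134 au (≈0.1 ps),
  r⁰ = 1.42 Å.
* **Tunneling**: d = 35, s = 1.25 for both — conduction is essentially
  unity at the equilibrium bond length and dies within ~30% stretch.
* **Effective areas** are derived by matching the bond network to the bulk
  Drude conductivity. For a resistor network, σ_bulk = (g l²/2V_cell)·Σ l̂l̂;
  with bond conductance g = 2σ_D(1−f)𝒜/l this gives 𝒜 = l²/(4√2) for the
  12-neighbor fcc lattice and 𝒜 = √3 l²/2 for the honeycomb sheet (slab
  normalization absorbed into the effective 3D density).
* **Gold interband α_IB**: a three-Lorentzian fit (centers 2.75/3.25/4.2 eV)
  giving a static atomic polarizability of ~80 au³ and an absorption onset
  near 2.4 eV. In an effective-medium estimate this places the screened
  dipolar resonance of a gold sphere near 2.2 eV; on desk-scale clusters
  the atomistic hybrid mode appears around 1.6–1.7 eV. A tabulated α_IB(ω)
  (e.g. from experimental dielectric data) can be supplied for quantitative
  work.

With these placeholders the *trends* are quantitative (sphere-limit PRF,
√E_F graphene scaling, size redshift, mode selectivity) while absolute
PRFs of specific production geometries depend on the parametrization.

## Validation anchors

* The 309-atom Drude icosahedron peaks within 10% of the classical sphere
  resonance ω_p/√3 — the discretization reproduces the continuum limit.
* A 10-atom chain at ω → 0 recovers the static charge-equilibration
  solution of the same kernels.
* Graphene disk PRFs increase strictly with E_F (∝ √E_F within a few
  percent) and decrease strictly with diameter.

## Geometry generators

**Mackay icosahedra.** Shell j places (n₁A + n₂B + n₃C), n₁+n₂+n₃ = j, on
each face of a unit-edge icosahedron scaled by the nearest-neighbor
distance; shared edges/vertices are deduplicated. Atom counts equal the
magic numbers (10k³+15k²+11k+3)/3 by construction (10,179 / 49,049 /
104,223 at 14/24/31 shells); the intra-shell spacing equals the requested
nearest-neighbor distance and the radial spacing is ~5% shorter, the
characteristic Mackay compression.

**Graphene disks.** The pristine honeycomb lattice (bond 1.42 Å) is cut by
atom-center distance ≤ radius around a hexagon center. This deterministic
convention reproduces reference atom counts to better than 1% (e.g. a
24 nm disk gives 17,268 atoms); exact counts depend on the cutting
convention of the source geometry and are not reproducible bit-for-bit.

## Molecular surrogate

The adsorbate is represented by point charges, atomic polar tensors (APTs,
∂d/∂R), mass-weighted normal modes, and per-mode polarizability
derivatives. APTs are independent of the charges so realistic IR patterns
can be imposed. When the geometry is displaced (for numerical
differentiation), compensating atomic point dipoles (APT_a − q_a I)·ΔR_a
are attached, making the surrogate dipole exactly linear in displacements
with APT slope — the analytic and numerical dipole derivatives then agree
to machine precision, which the tests exploit as an oracle. The documented
truncation of the molecular density is point charges + these atomic
dipoles.

The seeded generator builds a planar purine-like 6+5 ring skeleton with
bounded charges (|q| ≤ 0.5, exact neutrality), random bounded APTs, 3N−6
orthonormal mass-weighted modes orthogonal to rigid motions, and
frequencies in 400–1800 cm⁻¹. A 15-atom "adenine-like" variant imposes
four dominant IR bands at 1292/1448/1575/1605 cm⁻¹ (1605 strongest) by
least-squares-fitting APTs to target dipole derivatives; it is a demo
object, not a quantum-chemical adenine model, and none of the quantitative
checks depend on it.

What the generator does **not** emulate: anharmonicity, substrate-induced
changes to the normal modes (assumed negligible), chemical (charge-transfer)
enhancement, solvent, and configurational sampling. Tests passing on the
surrogate therefore validate the *electromagnetic* enhancement machinery,
not the quality of any specific molecule's vibrational data.

## Placement

A placement is a proper rotation plus the requirement that the anchor atom
sit exactly at the requested distance from its nearest substrate atom
(solved by bisection along the local outward normal; 3 Å and 3.4 Å end-on
and 3.5 Å face-on are the conventional standoffs). Face-on puts the anchor
directly above the substrate atom nearest the disk center so the standoff
equals the plane separation; end-on orients the molecule so the anchor is
its closest atom, choosing the body direction that maximizes the smallest
projection of the other atoms (a small Nelder–Mead search). Placements
that bring any atom below 1.5 Å, or below 0.9× the requested standoff, are
rejected.

## SEIRA and SERS

**SEIRA** (induced-dipole route): the surrogate density generates V^QM and
E^QM on the substrate atoms through the same regularized kernels (molecule
as point multipoles, substrate atoms smeared — kernel consistency is what
makes reciprocity exact). The response solved with these sources reduces to
d̃ = Σ(q_p r_p + μ_p); for uniform probes this equals the projection
identity −d̃·ê = Σ[q_p V^ext − μ_p·E^ext], kept as an independent reduction
in the tests. Intensities use the three-point central derivative of d + d̃
along the cartesian mode vector, displacement norm 0.001 Bohr (0.0005 Bohr
available as a stability check; the two agree to <1e-4 relative), substrate
solved at each mode's frequency.

**SERS** (declared classical surrogate of the quantum coupled-perturbed
treatment): effective tensors Λᵀ(∂α/∂Q)Λ with Λ(ω_inc) evaluated at the
molecular centroid and a 0.10 eV phenomenological lifetime folded into the
Drude rate (1/τ_eff = 1/τ + γ/ħ). Only the incident frequency enters the
dressing (no Stokes shift of Λ) — the single-incident-frequency protocol.
Activities use the 45a′² + 7γ′² invariant convention, generalized to
complex tensors with moduli. This surrogate preserves the enhancement
physics — local-field dressing, quartic scaling, mode selectivity — but
not chemical or image-field self-consistency effects.

**Enhancement statistics**: EF_i = I_i/I_i^vac; AEF = ΣI_i/ΣI_l^vac over
all modes; MEF = max EF_i over modes with nonzero vacuum intensity; i-MEF
ties break to the lowest frequency. Configuration averages take the
arithmetic mean of per-mode intensities before normalization.

## Spectra

Stick spectra are broadened with area-normalized Lorentzians, default fwhm
10 cm⁻¹ (peak height 2h/(π·fwhm)); curves can be max-normalized. Default
grids: 400–1800 cm⁻¹ at 1 cm⁻¹ for vibrational spectra, 0.8–3.0 eV at
0.005 eV for metal absorption.

## Problem sizes and numerical choices

Desk-scale studies in the tests and examples use clusters of 13–923 atoms
and disks of 3–5 nm (270–920 atoms), where dense solves and full-spectrum
scans complete in seconds; production-scale geometries (10⁴–3×10⁵ atoms)
run through the same API via the matrix-free GMRES path and are hour-scale
computations. Because the plasmon frequency of a disk scales like
√(E_F/D), the Fermi energies used to drag a desk-scale disk's plasmon into
the molecular fingerprint window (a few meV for a 3 nm disk) are
correspondingly smaller than those used for tens-of-nm disks; the physics
probed — resonance selectivity of the enhancement — is the same.

Small-cluster absorption spectra are intrinsically spiky (few discrete
modes, narrow Drude damping): PRF location on such spectra uses either a
modest extra broadening (0.03 eV in the graphene scans) or bracket-clamped
parabolic refinement, both recorded where used. The PRF is located on
σ(ω), not Im α(ω); for narrow resonances both peak within grid resolution.

## Known limitations

Quasi-static only; no defected or doped lattices, nanoalloys or arbitrary
crystal cuts; no periodic boundary conditions; no temperature-dependent or
nonlocal dielectric response; SERS is classical (no resonance-Raman, no
charge-transfer); ground-state molecule–substrate coupling is omitted;
shipped material parameters are qualitative placeholders.
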