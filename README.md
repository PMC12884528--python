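# plasmovib

Atomistic fluctuating-charge/fluctuating-dipole plasmonics, coupled to a
molecular vibrational surrogate to predict surface-enhanced infrared
(SEIRA) and Raman (SERS) intensities and enhancement factors.

## Who this is for

Researchers modelling molecules adsorbed on plasmonic substrates — metal
nanoparticles and gated graphene disks — who need frequency-dependent,
fully atomistic substrate response (thousands to hundreds of thousands of
atoms) without a quantum-mechanical treatment of the substrate, plus the
vibrational enhancement observables that spectroscopists report: per-mode
enhancement factors (EF), their intensity-weighted average (AEF), the
maximum (MEF) and the identity of the most-enhanced mode (i-MEF).

## The model

Every substrate atom *p* carries a complex frequency-dependent charge
*q_p*(ω). Charge flows between nearest neighbors by Drude conduction,
damped by a Fermi-like function *f*(*r*) that mimics quantum tunneling;
the charges interact through Gaussian-regularized Coulomb kernels. The
response solves the linear system

    [ K̄ T^qq − z_q(ω) I_N ] q(ω) = −K̄ V^ext(ω),

with K̄ the (column-sum-zero) conduction matrix built from
K_ij = [1 − f(r_ij)]·𝒜/r_ij on the neighbor graph, and
z_q(ω) = −ω(ωτ + i)/(2nτ) containing the relaxation time τ and the
effective electron density *n*. Column-sum-zero K̄ makes Σ_p q_p = 0 hold
structurally for any source. For graphene, *n* is linear in the tunable
Fermi energy, n = E_F/(π a₀ ħ v_F), which is what makes the disk plasmon
electrically tunable.

Noble metals additionally need the d-shell screening that pure Drude
misses: each atom then also carries a complex dipole μ_p governed by an
interband polarizability α_IB(ω) (z_μ = −1/α_IB), and charges and dipoles
couple through the full block system over the T^qq, T^qμ, T^μq, T^μμ
kernels.

On top of the substrate response:

* **SEIRA** — the adsorbed molecule's oscillating density induces a
  substrate dipole d̃; IR intensities come from the three-point numerical
  derivative (0.001 Bohr step) of the total dipole d + d̃ along each
  normal mode, with the substrate solved at the mode frequency.
  EF_i = I_i / I_i^vac.
* **SERS** — a classical dressed-tensor scheme: the local-field tensor
  Λ(ω_inc) at the molecular site dresses each polarizability derivative
  as Λᵀ(∂α/∂Q_i)Λ, giving the characteristic fourth-power local-field
  scaling (SEIRA is quadratic: EF_SERS = EF_SEIRA² in the scalar limit).

The molecule itself is a point-multipole vibrational surrogate (positions,
charges, atomic polar tensors, normal modes, polarizability derivatives)
with a seeded synthetic generator — no quantum-chemistry code required.

## Worked example

`examples/04_seira_enhancement.py` adsorbs an adenine-like 15-atom
surrogate flat on a 3 nm graphene disk at 3.5 Å and gates the disk so its
plasmon falls inside the molecular fingerprint region:

```
3 nm disk, E_F = 3.5 meV: PRF = 1558 cm^-1
AEF = 75.39   MEF = 190.79   i-MEF mode at 1575 cm^-1
  mode  1575.0 cm^-1: I_vac =  2495.69 km/mol, EF = 190.79
  mode  1605.0 cm^-1: I_vac =  6590.19 km/mol, EF = 108.06
  mode  1518.4 cm^-1: I_vac =    60.93 km/mol, EF = 101.88
  mode  1502.2 cm^-1: I_vac =    60.93 km/mol, EF =  64.59
```

The disk's plasmon resonance (PRF, 1558 cm⁻¹) acts as an IR antenna: the
modes closest to it are enhanced the most — the i-MEF lands at 1575 cm⁻¹,
right next to the PRF — while modes far from resonance stay near their
gas-phase intensities. Retuning the Fermi energy moves the PRF and drags
the i-MEF with it (`tests/test_seira_sers.py::TestSeira::test_imef_tracks_prf`).

The other examples build the substrate geometries (magic-number icosahedra,
honeycomb disks), locate gold and graphene plasmon resonances, and contrast
on- versus off-resonance SERS.

## Layout

```
src/plasmovib/     structures, materials, kernels, response, molecule,
                   seira_sers, spectra, units, cli
examples/          one narrative script per capability
tests/             pytest suite
scripts/           acceptance.py
docs/methods.md    model assumptions, parameters, numerical choices
```

A thin CLI mirrors the library (`plasmovib build|respond|prf|seira|sers|
fixture|convolve`); the Python API is the primary interface.
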