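"""Absorption spectrum and plasmon resonance of a small gold cluster.

Solves the charge+dipole (interband-corrected) response of a 55-atom
icosahedron for uniform fields over a frequency grid and locates the
plasmon resonance frequency (PRF) on the orientation-averaged cross-section.
The pure-Drude run shows what the interband screening changes.
"""

import numpy as np

import plasmovib as pv

ico = pv.build_mackay_icosahedron(2)
grid = np.arange(0.8, 3.0, 0.02)

model = pv.SubstrateModel(ico, pv.materials.gold(), mode="wfqfmu")
spec = pv.absorption_spectrum(model, grid)
print(f"55-atom gold cluster, charge+dipole model: PRF = {spec.prf_ev:.3f} eV")

drude = pv.SubstrateModel(ico, pv.materials.drude_gold(), mode="wfq")
spec_d = pv.absorption_spectrum(drude, np.arange(3.0, 8.0, 0.05))
print(f"same cluster, Drude charges only:          PRF = {spec_d.prf_ev:.3f} eV")

print("The d-shell (interband) dipoles screen the bare Drude plasmon and "
      "pull the resonance from the UV down into the visible, as in real "
      "gold; the absolute position depends on the interband parametrization.")
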