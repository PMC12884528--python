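"""Unit conversions (CODATA 2018), centralized.

Internally the library works in Hartree atomic units; Å, eV and cm⁻¹
appear only at the public interfaces.
"""

HARTREE_EV = 27.211386245988       # 1 Hartree in eV
BOHR_ANGSTROM = 0.529177210903     # 1 Bohr in Å
EV_CM = 8065.543937                # 1 eV in cm⁻¹
HARTREE_CM = HARTREE_EV * EV_CM    # 1 Hartree in cm⁻¹
C_AU = 137.035999084               # speed of light in au
AMU_AU = 1822.888486209            # 1 amu in electron masses
AU_TIME_FS = 0.02418884326509      # 1 au of time in fs


def ev_to_au(x):
    return x / HARTREE_EV


def au_to_ev(x):
    return x * HARTREE_EV


def cm_to_au(x):
    return x / HARTREE_CM


def au_to_cm(x):
    return x * HARTREE_CM


def angstrom_to_bohr(x):
    return x / BOHR_ANGSTROM


def bohr_to_angstrom(x):
    return x * BOHR_ANGSTROM


def ev_to_cm(x):
    return x * EV_CM


def cm_to_ev(x):
    return x / EV_CM
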