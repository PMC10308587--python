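"""Unit conversions.

All internal arithmetic is done in Hartree atomic units; angstrom, eV and
cm^-1 appear only at the I/O boundary.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988

# 1 cm^-1 in Hartree
HARTREE_PER_CM1 = 4.556335252912e-6
CM1_PER_HARTREE = 1.0 / HARTREE_PER_CM1

SPEED_OF_LIGHT_AU = 137.035999084


def ang_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_ang(x):
    return x * ANGSTROM_PER_BOHR


def ev_to_hartree(x):
    return x * HARTREE_PER_EV


def hartree_to_ev(x):
    return x * EV_PER_HARTREE


def cm1_to_hartree(x):
    return x * HARTREE_PER_CM1
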