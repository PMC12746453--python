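"""Atomic-unit constants and conversion helpers.

All internal quantities in this package are in Hartree atomic units
(hartree, bohr, atomic time unit, atomic field unit).  Conversions are
applied only at input/output boundaries.
"""

# CODATA 2018
HARTREE_EV = 27.211386245988          # 1 hartree in eV
BOHR_ANGSTROM = 0.529177210903        # 1 bohr in Angstrom
AUT_FS = 0.024188843265857            # 1 atomic time unit in fs
AMU_ME = 1822.888486209               # 1 unified amu in electron masses
WAVENUMBER_HARTREE = 4.556335252912e-6  # 1 cm^-1 in hartree


def ev_to_au(e):
    return e / HARTREE_EV


def au_to_ev(e):
    return e * HARTREE_EV


def fs_to_au(t):
    return t / AUT_FS


def au_to_fs(t):
    return t * AUT_FS


def angstrom_to_bohr(r):
    return r / BOHR_ANGSTROM


def bohr_to_angstrom(r):
    return r * BOHR_ANGSTROM


def amu_to_au(m):
    return m * AMU_ME
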