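"""Bundled element data: standard atomic weights and radii.

Masses are IUPAC standard atomic weights (abridged to four decimals), not
most-abundant-isotope masses. Covalent radii follow Cordero et al.;
van der Waals radii follow Bondi (with the common extensions). Units: amu, Å.
"""

from __future__ import annotations

from .errors import UsageError

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Sc": 44.956, "Ti": 47.867, "V": 50.942,
    "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38, "Ga": 69.723, "Ge": 72.630, "As": 74.922,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798,
    "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224, "Nb": 92.906,
    "Mo": 95.95, "Ru": 101.07, "Rh": 102.91, "Pd": 106.42, "Ag": 107.87,
    "Cd": 112.41, "In": 114.82, "Sn": 118.71, "Sb": 121.76, "Te": 127.60,
    "I": 126.90, "Xe": 131.29,
    "Cs": 132.91, "Ba": 137.33, "La": 138.91, "W": 183.84, "Re": 186.21,
    "Os": 190.23, "Ir": 192.22, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
    "Tl": 204.38, "Pb": 207.2, "Bi": 208.98,
}

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Cu": 1.32, "Zn": 1.22,
    "Br": 1.20, "I": 1.39,
}
_DEFAULT_COVALENT = 1.50

VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "Br": 1.85, "I": 1.98, "Na": 2.27, "K": 2.75, "Li": 1.82, "Mg": 1.73,
    "Zn": 1.39, "Cu": 1.40,
}
_DEFAULT_VDW = 1.80


def is_known_element(symbol: str) -> bool:
    return symbol in ATOMIC_MASSES


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in amu; UsageError for unknown symbols."""
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise UsageError(f"unknown element symbol: {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    return COVALENT_RADII.get(symbol, _DEFAULT_COVALENT)


def vdw_radius(symbol: str) -> float:
    return VDW_RADII.get(symbol, _DEFAULT_VDW)
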