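"""Ideal-gas RRHO thermochemistry with Truhlar's quasi-harmonic floor.

Gibbs free energies are assembled as G = E_elec + H_corr − T·S_total from
translational (Sackur–Tetrode), rotational (classical rigid rotor),
vibrational (harmonic oscillator) and electronic contributions at a given
temperature and pressure (defaults 298.15 K, 1 atm — the Gaussian
standard state).

The quasi-harmonic treatment raises every vibrational wavenumber below a
floor (default 100 cm⁻¹) to the floor when evaluating vibrational
*entropy*, which tames the divergence of the harmonic-oscillator entropy
for soft modes. Zero-point energy and thermal enthalpy use the raw
wavenumbers by default; set qh_apply="all" to floor those too.

Physical constants: exact SI values via scipy (h, c, k_B, N_A are exactly
defined); the gas constant is pinned to R = 1.987204259e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import constants as sc

from .chem import Molecule
from .errors import UsageError, ValidationError

R_KCAL = 1.987204259e-3          # kcal / (mol K)
KCAL_PER_J = 1.0 / 4184.0
# energy (kcal/mol) of one photon-equivalent per cm^-1: h c ṽ N_A
KCAL_PER_WAVENUMBER = sc.h * sc.c * 100.0 * sc.N_A * KCAL_PER_J
# vibrational temperature (K) per cm^-1: h c ṽ / k_B
K_PER_WAVENUMBER = sc.h * sc.c * 100.0 / sc.k
_LINEAR_TOL = 1e-4               # Å, collinearity threshold


@dataclass
class FrequencySet:
    """Real vibrational wavenumbers (cm⁻¹) plus a count of discarded imaginary modes."""

    wavenumbers: list[float] = field(default_factory=list)
    n_imaginary: int = 0

    def __post_init__(self) -> None:
        self.wavenumbers = [float(w) for w in self.wavenumbers]
        if any(w <= 0 or not math.isfinite(w) for w in self.wavenumbers):
            raise UsageError("stored wavenumbers must be positive and finite "
                             "(imaginary modes are counted, not stored)")
        if self.n_imaginary < 0:
            raise UsageError("n_imaginary cannot be negative")


def quasiharmonic_floor(freqs: FrequencySet, floor: float = 100.0) -> FrequencySet:
    """Raise every wavenumber strictly below `floor` to `floor`.

    The boundary is exclusive: a mode at exactly the floor is untouched.
    Returns a new FrequencySet; floored indices are available via
    floored_indices().
    """
    if floor <= 0:
        raise UsageError("quasi-harmonic floor must be positive")
    return FrequencySet([max(w, floor) for w in freqs.wavenumbers], freqs.n_imaginary)


def floored_indices(freqs: FrequencySet, floor: float = 100.0) -> list[int]:
    return [i for i, w in enumerate(freqs.wavenumbers) if w < floor]


def zpe(freqs: FrequencySet) -> float:
    """Zero-point vibrational energy, ½ Σ h c ṽ N_A, in kcal/mol."""
    return 0.5 * KCAL_PER_WAVENUMBER * sum(freqs.wavenumbers)


@dataclass
class ThermoInput:
    molecule: Molecule
    e_elec: float                      # kcal/mol
    freqs: FrequencySet
    T: float = 298.15                  # K
    P: float = 1.0                     # atm
    sigma: int = 1                     # rotational symmetry number
    qh_floor: float = 100.0            # cm^-1
    qh_apply: str = "entropy"          # "entropy" | "all"
    is_ts: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise UsageError("temperature must be positive")
        if self.P <= 0:
            raise UsageError("pressure must be positive")
        if self.sigma < 1:
            raise UsageError("symmetry number must be >= 1")
        if self.qh_apply not in ("entropy", "all"):
            raise UsageError("qh_apply must be 'entropy' or 'all'")


@dataclass
class ThermoResult:
    ZPE: float                 # kcal/mol
    H_corr: float              # kcal/mol (ZPE + thermal E + RT)
    S_trans: float             # kcal/(mol K)
    S_rot: float
    S_vib: float
    S_elec: float
    G: float                   # kcal/mol
    qh_applied: list[int]      # indices of floored modes
    E_elec: float = 0.0
    T: float = 298.15

    @property
    def S_total(self) -> float:
        return self.S_trans + self.S_rot + self.S_vib + self.S_elec


def _is_linear(coords: np.ndarray) -> bool:
    if len(coords) < 3:
        return True
    c = coords - coords.mean(axis=0)
    # residual off the principal axis must be below the collinearity tolerance
    _, s, _ = np.linalg.svd(c, full_matrices=False)
    return bool(s[1] <= _LINEAR_TOL * math.sqrt(len(coords)))


def _moments_of_inertia(masses: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Principal moments, amu·Å² (ascending)."""
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    Ixx = (masses * (y**2 + z**2)).sum()
    Iyy = (masses * (x**2 + z**2)).sum()
    Izz = (masses * (x**2 + y**2)).sum()
    Ixy = -(masses * x * y).sum()
    Ixz = -(masses * x * z).sum()
    Iyz = -(masses * y * z).sum()
    tensor = np.array([[Ixx, Ixy, Ixz], [Ixy, Iyy, Iyz], [Ixz, Iyz, Izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def _s_trans(mass_amu: float, T: float, P_atm: float) -> float:
    """Sackur–Tetrode translational entropy, kcal/(mol K)."""
    m = mass_amu * 1e-3 / sc.N_A            # kg
    P = P_atm * sc.atm                       # Pa
    q = (2.0 * math.pi * m * sc.k * T / sc.h**2) ** 1.5 * (sc.k * T / P)
    return R_KCAL * (math.log(q) + 2.5)


def _rotational(masses, coords, T, sigma):
    """Returns (S_rot kcal/(mol K), E_rot kcal/mol)."""
    if len(coords) == 1:
        return 0.0, 0.0
    I = _moments_of_inertia(np.asarray(masses, float), np.asarray(coords, float))
    I_SI = I * 1e-3 / sc.N_A * 1e-20        # kg m^2
    hbar = sc.hbar
    if _is_linear(coords):
        theta = hbar**2 / (2.0 * I_SI[2] * sc.k)
        q = T / (sigma * theta)
        return R_KCAL * (math.log(q) + 1.0), R_KCAL * T
    thetas = hbar**2 / (2.0 * I_SI * sc.k)
    q = math.sqrt(math.pi) / sigma * math.sqrt(T**3 / (thetas[0] * thetas[1] * thetas[2]))
    return R_KCAL * (math.log(q) + 1.5), 1.5 * R_KCAL * T


def _vib_thermal_energy(wavenumbers, T) -> float:
    """Thermal vibrational energy above ZPE, kcal/mol."""
    e = 0.0
    for w in wavenumbers:
        theta = K_PER_WAVENUMBER * w
        e += R_KCAL * theta / math.expm1(theta / T)
    return e


def _s_vib(wavenumbers, T) -> float:
    s = 0.0
    for w in wavenumbers:
        x = K_PER_WAVENUMBER * w / T
        s += R_KCAL * (x / math.expm1(x) - math.log1p(-math.exp(-x)))
    return s


def gibbs(inp: ThermoInput) -> ThermoResult:
    """Full RRHO Gibbs free energy with the quasi-harmonic entropy floor.

    For a transition-state record (is_ts=True) exactly one imaginary mode
    must have been discarded from the frequency set; it never enters any
    sum. The returned result satisfies G = E_elec + H_corr − T·S_total
    identically by construction.
    """
    mol = inp.molecule
    if len(mol) < 1:
        raise UsageError("molecule must contain at least one atom")
    if np.any(mol.masses <= 0):
        raise UsageError("all atomic masses must be positive")
    expected_imag = 1 if inp.is_ts else 0
    if inp.freqs.n_imaginary != expected_imag:
        raise ValidationError(
            f"{'TS' if inp.is_ts else 'minimum'} record expects "
            f"{expected_imag} imaginary mode(s), got {inp.freqs.n_imaginary}")

    floored = quasiharmonic_floor(inp.freqs, inp.qh_floor)
    qh_idx = floored_indices(inp.freqs, inp.qh_floor)
    raw_w = (floored if inp.qh_apply == "all" else inp.freqs).wavenumbers

    T = inp.T
    zpe_val = zpe(FrequencySet(raw_w))
    e_thermal = 1.5 * R_KCAL * T + _vib_thermal_energy(raw_w, T)
    s_rot, e_rot = _rotational(mol.masses, mol.coords, T, inp.sigma)
    e_thermal += e_rot
    h_corr = zpe_val + e_thermal + R_KCAL * T   # +RT: H = E + PV for ideal gas

    s_trans = _s_trans(float(mol.masses.sum()), T, inp.P)
    s_vib = _s_vib(floored.wavenumbers, T)
    s_elec = R_KCAL * math.log(mol.multiplicity)
    s_total = s_trans + s_rot + s_vib + s_elec

    g = inp.e_elec + h_corr - T * s_total
    return ThermoResult(ZPE=zpe_val, H_corr=h_corr, S_trans=s_trans, S_rot=s_rot,
                        S_vib=s_vib, S_elec=s_elec, G=g, qh_applied=qh_idx,
                        E_elec=inp.e_elec, T=T)
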