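"""Boltzmann statistics over transition-state ensembles.

The enantiomeric excess predicted for a stereodetermining step follows
from the Boltzmann populations of all competing transition states at the
reaction temperature: ee% = 100 · |Σ w(R) − Σ w(S)|. For exactly two
enantiomeric transition states this reduces to the closed form
ee = 100 · tanh(ΔΔG‡ / 2RT).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .thermochem import R_KCAL

STEREO_OUTCOMES = ("R", "S")
_RACEMIC_TOL = 1e-9


@dataclass
class TSRecord:
    label: str
    stereo_outcome: str   # "R" | "S"
    G: float              # kcal/mol

    def __post_init__(self) -> None:
        if self.stereo_outcome not in STEREO_OUTCOMES:
            raise UsageError(f"stereo outcome must be R or S, got {self.stereo_outcome!r}")
        if not math.isfinite(self.G):
            raise UsageError("TS free energy must be finite")


@dataclass
class EEResult:
    ee_percent: float          # [0, 100]
    major: str                 # "R" | "S" | "racemic"
    weights: dict              # label -> Boltzmann population
    ddg: float = float("nan")  # G(minor lowest) - G(major lowest), two-outcome case


def boltzmann_weights(energies, T: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann populations, overflow-safe via a min-shift."""
    energies = np.asarray(list(energies), dtype=float)
    if energies.size == 0:
        raise UsageError("at least one energy is required")
    if T <= 0:
        raise UsageError("temperature must be positive")
    shifted = energies - energies.min()
    w = np.exp(-shifted / (R_KCAL * T))
    return w / w.sum()


def ee_from_ensemble(ts: list[TSRecord], T: float = 298.15) -> EEResult:
    """Enantiomeric excess from the Boltzmann distribution over an ensemble.

    All supplied transition states contribute, not only the lowest pair;
    a two-member ensemble reproduces 100·tanh(ΔΔG/2RT) exactly.
    """
    if T <= 0:
        raise UsageError("temperature must be positive")
    if not ts:
        raise UsageError("empty transition-state ensemble")
    outcomes = {r.stereo_outcome for r in ts}
    w = boltzmann_weights([r.G for r in ts], T)
    weights = {r.label: float(x) for r, x in zip(ts, w)}
    if len(outcomes) < 2:
        warnings.warn("degenerate ensemble: only one stereo outcome present; ee = 100%",
                      stacklevel=2)
        only = next(iter(outcomes))
        return EEResult(100.0, only, weights, ddg=math.inf)
    w_r = float(sum(x for r, x in zip(ts, w) if r.stereo_outcome == "R"))
    w_s = 1.0 - w_r
    ee = 100.0 * abs(w_r - w_s)
    if abs(w_r - w_s) < _RACEMIC_TOL:
        major = "racemic"
    else:
        major = "R" if w_r > w_s else "S"
    g_r = min(r.G for r in ts if r.stereo_outcome == "R")
    g_s = min(r.G for r in ts if r.stereo_outcome == "S")
    return EEResult(ee, major, weights, ddg=abs(g_r - g_s))


def activation_free_energy(ts_G: float, reactant_Gs) -> float:
    """ΔG‡ relative to separated starting materials: G_TS − Σ G_reactants."""
    reactant_Gs = list(reactant_Gs)
    if not reactant_Gs:
        raise UsageError("at least one reactant free energy is required")
    return ts_G - sum(reactant_Gs)
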