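"""Conformer ensemble generation, deduplication, and shortlist selection.

The stochastic torsional search mirrors the contract of the screening
protocol: random torsion perturbations from a seeded generator, rejection
of clashed geometries (any nonbonded pair closer than 0.7 × the sum of
covalent radii), rejection of duplicates (aligned heavy-atom RMSD below
0.25 Å to an already accepted conformer), scoring by a pluggable energy
backend, and termination after an iteration limit or a run of consecutive
rejections. Both limits default to 1000. Runs are bit-reproducible from
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import periodic
from .chem import Bond, Conformer, EnergyBackend, Molecule, find_rotatable_bonds
from .errors import UsageError
from .geometry import rmsd_heavy, rotation_about_axis

DUPLICATE_RMSD = 0.25            # Å, post-search library deduplication
PROPOSAL_DUPLICATE_RMSD = 0.01   # Å, in-search re-draw detection only
CLASH_FACTOR = 0.7               # × sum of covalent radii


@dataclass
class SearchLimits:
    iteration_limit: int = 1000
    rejection_limit: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iteration_limit < 1 or self.rejection_limit < 1:
            raise UsageError("search limits must be >= 1")


@dataclass
class ConformerLibrary:
    molecule: Molecule
    conformers: list[Conformer]
    metadata: dict = field(default_factory=dict)
    warning: Optional[str] = None

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def ids(self) -> list[str]:
        return [c.id for c in self.conformers]


def _moving_side(mol: Molecule, bond: Bond) -> list[int]:
    """Atoms on the j-side of a rotatable (bridge) bond."""
    g = mol.graph()
    g.remove_edge(bond.i, bond.j)
    return sorted(nx.node_connected_component(g, bond.j))


def _set_torsion(mol: Molecule, coords: np.ndarray, bond: Bond,
                 moving: Sequence[int], angle_deg: float) -> np.ndarray:
    """Rotate the moving side about the bond axis by angle_deg (relative)."""
    axis_point = coords[bond.i]
    axis_dir = coords[bond.j] - coords[bond.i]
    R, t = rotation_about_axis(axis_point, axis_dir, angle_deg)
    out = coords.copy()
    out[list(moving)] = coords[list(moving)] @ R.T + t
    return out


def has_clash(mol: Molecule, coords: np.ndarray,
              factor: float = CLASH_FACTOR) -> bool:
    """True if any nonbonded atom pair sits closer than factor × (rcov_i + rcov_j)."""
    n = len(mol)
    bonded = {frozenset((b.i, b.j)) for b in mol.bonds}
    rcov = np.array([periodic.covalent_radius(a.element) for a in mol.atoms])
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((i, j)) in bonded:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < factor * (rcov[i] + rcov[j]):
                return True
    return False


def stochastic_search(mol: Molecule, limits: SearchLimits,
                      backend: EnergyBackend,
                      duplicate_rmsd: float = PROPOSAL_DUPLICATE_RMSD) -> ConformerLibrary:
    """Seeded stochastic torsional search.

    Each iteration draws one uniform random angle per rotatable bond,
    applies them to the input geometry, rejects the proposal if it clashes
    or essentially re-draws an accepted geometry (aligned heavy-atom RMSD
    below `duplicate_rmsd`), and otherwise scores and accepts it. Stops at
    the iteration limit or after `rejection_limit` consecutive rejections.
    Output is sorted by energy (ascending) with stable ids; identical
    inputs and seed give identical libraries.

    The in-search duplicate criterion is deliberately tight: it only
    guards against re-drawn proposals so that sampling density is
    preserved. The protocol's 0.25 Å duplicate pruning is a separate,
    post-search step (see deduplicate).

    A molecule with no rotatable bonds yields a single-conformer library
    with a warning flag instead of an error.
    """
    rot_bonds = find_rotatable_bonds(mol)
    rng = np.random.default_rng(limits.seed)
    base = mol.coords
    backend_name = getattr(backend, "name", type(backend).__name__)
    metadata = {
        "seed": limits.seed,
        "iteration_limit": limits.iteration_limit,
        "rejection_limit": limits.rejection_limit,
        "backend": backend_name,
        "duplicate_rmsd": duplicate_rmsd,
        "n_rotatable_bonds": len(rot_bonds),
    }
    start = Conformer(mol, base, energy=float(backend(mol, base)), id="c0000")
    if not rot_bonds:
        return ConformerLibrary(mol, [start], metadata,
                                warning="no rotatable bonds; returning input geometry only")
    moving_sides = [_moving_side(mol, b) for b in rot_bonds]

    accepted = [start]
    consecutive_rejections = 0
    iterations = 0
    while iterations < limits.iteration_limit:
        if consecutive_rejections >= limits.rejection_limit:
            break
        iterations += 1
        angles = rng.uniform(0.0, 360.0, size=len(rot_bonds))
        coords = base
        for bond, moving, ang in zip(rot_bonds, moving_sides, angles):
            coords = _set_torsion(mol, coords, bond, moving, float(ang))
        if has_clash(mol, coords):
            consecutive_rejections += 1
            continue
        cand = Conformer(mol, coords)
        if any(rmsd_heavy(cand, acc) < duplicate_rmsd for acc in accepted):
            consecutive_rejections += 1
            continue
        cand.energy = float(backend(mol, coords))
        cand.id = f"c{len(accepted):04d}"
        accepted.append(cand)
        consecutive_rejections = 0

    metadata["iterations_run"] = iterations
    ordered = sorted(accepted, key=lambda c: c.energy)
    return ConformerLibrary(mol, ordered, metadata)


def deduplicate(lib: ConformerLibrary,
                threshold: float = DUPLICATE_RMSD) -> ConformerLibrary:
    """Greedy duplicate removal in ascending energy order.

    A conformer survives iff its aligned heavy-atom RMSD to every
    already-kept conformer is >= threshold, so the lowest-energy member of
    each duplicate cluster is the representative. Idempotent.
    """
    if any(c.energy is None for c in lib.conformers):
        raise UsageError("deduplicate requires energies on all conformers")
    ordered = sorted(lib.conformers, key=lambda c: c.energy)
    kept: list[Conformer] = []
    for cand in ordered:
        if all(rmsd_heavy(cand, k) >= threshold for k in kept):
            kept.append(cand)
    metadata = dict(lib.metadata)
    metadata["dedup_threshold"] = threshold
    metadata["n_removed_duplicates"] = len(lib.conformers) - len(kept)
    return ConformerLibrary(lib.molecule, kept, metadata, lib.warning)


def select_for_qm(lib: ConformerLibrary, matching_ids: set,
                  n_low: int = 20) -> list[Conformer]:
    """Union of the n_low lowest-energy conformers and all matching ones.

    Mirrors the screening protocol's handoff rule: the lowest 20 plus the
    matching active conformers go on to quantum-mechanical refinement.
    Output is energy-ordered and free of duplicates.
    """
    if n_low < 0:
        raise UsageError("n_low must be non-negative")
    known = set(lib.ids())
    unknown = set(matching_ids) - known
    if unknown:
        raise UsageError(f"unknown conformer ids in matching set: {sorted(unknown)}")
    ordered = sorted(lib.conformers, key=lambda c: c.energy)
    chosen_ids = {c.id for c in ordered[:n_low]} | set(matching_ids)
    return [c for c in ordered if c.id in chosen_ids]
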