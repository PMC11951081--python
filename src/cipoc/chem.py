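"""Molecular data model: atoms, molecules, conformers, and energy backends.

Units are fixed package-wide: Å for coordinates, kcal/mol for energies,
amu for masses. No unit arguments appear anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

from . import periodic
from .errors import UsageError


@dataclass
class Atom:
    """One atom: element symbol, Cartesian position (Å), mass (amu).

    The mass is filled in from the bundled standard-atomic-weight table
    unless given explicitly.
    """

    element: str
    position: np.ndarray
    mass: float = 0.0
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if not periodic.is_known_element(self.element):
            raise UsageError(f"unknown element symbol: {self.element!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise UsageError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise UsageError("atom position must be finite")
        if self.mass == 0.0:
            self.mass = periodic.atomic_mass(self.element)
        if self.mass <= 0:
            raise UsageError("atom mass must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class Bond(NamedTuple):
    i: int
    j: int
    order: int = 1
    aromatic: bool = False


@dataclass
class Molecule:
    """An ordered list of atoms plus optional connectivity.

    Atom order is stable across read/write round-trips; every index-based
    reference elsewhere in the package (forming bonds, fragment partitions,
    feature source atoms) relies on that.
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    charge: int = 0
    multiplicity: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        fixed = []
        for b in self.bonds:
            b = Bond(*b)
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise UsageError(f"bond index out of range: {b}")
            if b.i == b.j:
                raise UsageError(f"self-bond not allowed: {b}")
            fixed.append(b)
        self.bonds = fixed
        if self.multiplicity < 1:
            raise UsageError("multiplicity must be a positive integer")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([k for k, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise UsageError("coordinate array shape does not match atom count")
        atoms = [
            Atom(a.element, c, a.mass, a.formal_charge)
            for a, c in zip(self.atoms, coords)
        ]
        return Molecule(atoms, list(self.bonds), self.charge, self.multiplicity, self.name)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return sorted(out)


@dataclass
class Conformer:
    """One geometry of a molecule, with an optional backend energy (kcal/mol)."""

    molecule: Molecule
    coordinates: np.ndarray
    energy: Optional[float] = None
    id: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.molecule), 3):
            raise UsageError("conformer coordinate count must equal atom count")
        if self.energy is not None and not math.isfinite(self.energy):
            raise UsageError("conformer energy must be finite when set")

    def as_molecule(self) -> Molecule:
        return self.molecule.with_coords(self.coordinates)


# An energy backend maps (molecule, coordinates) -> kcal/mol. It must be
# deterministic and invariant under rigid motion of the coordinates.
EnergyBackend = Callable[[Molecule, np.ndarray], float]


def find_rotatable_bonds(mol: Molecule) -> list[Bond]:
    """Acyclic single non-aromatic bonds between two non-terminal atoms.

    Acyclicity is decided by bridge detection on the bond graph, so ring
    bonds are never rotatable.
    """
    g = mol.graph()
    bridges = {frozenset(e) for e in nx.bridges(g)} if g.number_of_edges() else set()
    out = []
    for b in mol.bonds:
        if b.order != 1 or b.aromatic:
            continue
        if frozenset((b.i, b.j)) not in bridges:
            continue
        if g.degree(b.i) < 2 or g.degree(b.j) < 2:
            continue
        out.append(b)
    return out


class ToyForceField:
    """Toy energy backend: hard-sphere clash penalty plus 3-fold cosine torsions.

    Stands in for a molecular-mechanics scorer so the screening pipeline can
    be exercised end to end; it is not chemically accurate. The energy
    depends only on interatomic distances and dihedral angles, so it is
    exactly invariant under rigid motion.

    E = sum_clash k_clash * (r0 - r)^2   for nonbonded pairs with r < r0,
        r0 = scale * (rcov_i + rcov_j)
      + sum_torsions (V3/2) * (1 + cos 3*phi)   over rotatable bonds.
    """

    name = "toy-hardsphere-cosine"

    def __init__(self, k_clash: float = 50.0, clash_scale: float = 0.9, v3: float = 2.0):
        self.k_clash = k_clash
        self.clash_scale = clash_scale
        self.v3 = v3

    def __call__(self, mol: Molecule, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float)
        n = len(mol)
        bonded = {frozenset((b.i, b.j)) for b in mol.bonds}
        # 1-3 pairs are excluded from the clash term
        one_three = set()
        for k in range(n):
            nb = mol.neighbors(k)
            for a in nb:
                for b in nb:
                    if a < b:
                        one_three.add(frozenset((a, b)))
        rcov = np.array([periodic.covalent_radius(a.element) for a in mol.atoms])
        e = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                key = frozenset((i, j))
                if key in bonded or key in one_three:
                    continue
                r0 = self.clash_scale * (rcov[i] + rcov[j])
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if r < r0:
                    e += self.k_clash * (r0 - r) ** 2
        for b in find_rotatable_bonds(mol):
            a_ref = min(k for k in mol.neighbors(b.i) if k != b.j)
            b_ref = min(k for k in mol.neighbors(b.j) if k != b.i)
            phi = _dihedral(coords[a_ref], coords[b.i], coords[b.j], coords[b_ref])
            e += 0.5 * self.v3 * (1.0 + math.cos(3.0 * phi))
        return e


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in radians."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.atan2(y, x)
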