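"""Deterministic test-surface generators.

Everything here is synthetic and idealized: planar fragments, standard-ish
bond lengths, and rigid "cumulated" skeletons (all-double-bond backbones)
whose only purpose is to make planted geometry exact in every accessible
conformation. Chemical realism is explicitly not the goal — these objects
exercise the screening pipeline with known ground truth.

The reference template is a malonate-like nucleophile poised 2.2 Å from a
nitroalkene-like electrophile (echoing the forming C–C distances of the
coupling transition state), with an H-bond-donor site at the nitro group
and a double-contact H-bond-acceptor site at the nucleophile carbonyls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .catalophore import CGM, build_cgm
from .chem import Atom, Bond, Molecule
from .errors import UsageError
from .io import write_sdf
from .thermochem import FrequencySet, ThermoInput
from .theozyme import AnchorSpec, CatalyticSite, TSTemplate

FORMING_CC = 2.2  # Å

TRUTH_LABELS = ("matcher", "decoy-geometry", "decoy-kind", "inert")
DEFAULT_FRACTIONS = {label: 0.25 for label in TRUTH_LABELS}


def _mol(name, rows, bonds, charge=0):
    atoms = [Atom(sym, np.array(xyz, float), formal_charge=fc)
             for sym, xyz, fc in rows]
    return Molecule(atoms, [Bond(*b) for b in bonds], charge=charge, name=name)


def make_reference_template(double_hba: bool = True) -> TSTemplate:
    """Reference theozyme template with a 2.2 Å forming C–C bond.

    Binding mode BMA, face Re, rotamer 0. The HBA site is double-contact
    by default (both nucleophile carbonyl oxygens), giving a 3-feature CGM;
    pass double_hba=False for the 2-feature single-contact variant.
    """
    electrophile = _mol(
        "nitroalkene-like",
        [("C", (0.00, 0.00, 0.00), 0),     # attacked carbon, on the forming axis
         ("C", (1.40, 0.00, 0.00), 0),
         ("N", (2.10, 1.15, 0.00), 1),
         ("O", (3.25, 1.45, 0.20), 0),
         ("O", (1.65, 2.20, -0.20), -1),
         ("H", (-0.55, -0.85, 0.40), 0),
         ("H", (1.95, -0.90, -0.10), 0)],
        [(0, 1, 2), (1, 2, 1), (2, 3, 2), (2, 4, 1), (0, 5, 1), (1, 6, 1)],
    )
    nucleophile = _mol(
        "malonate-like",
        [("C", (0.00, 0.00, 2.20), 0),     # nucleophilic carbon, on the forming axis
         ("C", (1.25, 0.70, 2.60), 0),
         ("O", (2.35, 0.15, 2.75), 0),
         ("H", (1.20, 1.78, 2.72), 0),
         ("C", (-1.25, 0.70, 2.60), 0),
         ("O", (-2.35, 0.15, 2.75), 0),
         ("H", (-1.20, 1.78, 2.72), 0),
         ("H", (0.00, -0.95, 2.75), 0)],
        [(0, 1, 1), (1, 2, 2), (1, 3, 1), (0, 4, 1), (4, 5, 2), (4, 6, 1), (0, 7, 1)],
    )
    return TSTemplate(
        nucleophile=nucleophile,
        electrophile=electrophile,
        sites={"HBD": CatalyticSite("HBD", double_contact=False),
               "HBA": CatalyticSite("HBA", double_contact=double_hba)},
        anchors={"nucleophile": AnchorSpec((2, 5), 0, standoff=2.0),
                 "electrophile": AnchorSpec((3, 4), 2, standoff=2.0)},
        forming_bond=(0, 0),
        binding_mode="BMA",
        face="Re",
        rotamer_deg=0.0,
    )


def make_reference_cgm(tolerances=None, **policy) -> CGM:
    """CGM built from the reference template (3 features with defaults)."""
    return build_cgm(make_reference_template(), tolerances=tolerances, **policy)


# ---------------------------------------------------------------- planted library

def _matcher_skeleton(cgm: CGM) -> Molecule:
    """A rigid molecule whose features sit exactly on the CGM positions.

    Feature atoms are placed on the CGM feature points (HBD hydrogen on
    the HBD point, carbonyl oxygens on the HBA points); the backbone arcs
    away from the substrate's excluded volume. All skeleton bonds are
    double so the molecule has no rotatable bonds.
    """
    hbd = next(f for f in cgm.features if f.kind == "HBD")
    hbas = [f for f in cgm.features if f.kind == "HBA"]
    # outward = away from the substrate, i.e. opposite the feature's H-bond direction
    out_hbd = -hbd.direction
    h0 = hbd.position
    o1 = h0 + 0.96 * out_hbd
    rows = [("H", tuple(h0), 0), ("O", tuple(o1), 0)]
    bonds = [(0, 1, 1)]
    bridge_anchor = o1 + 1.4 * out_hbd
    for f in hbas:
        c_back = f.position - 1.23 * f.direction      # carbonyl carbon behind the O
        mid = 0.5 * (bridge_anchor + c_back) + 1.6 * out_hbd  # bow the bridge outward
        rows.append(("C", tuple(mid), 0))
        rows.append(("C", tuple(c_back), 0))
        rows.append(("O", tuple(f.position), 0))
        i_mid, i_c, i_o = len(rows) - 3, len(rows) - 2, len(rows) - 1
        bonds += [(1, i_mid, 2), (i_mid, i_c, 2), (i_c, i_o, 2)]
    return _mol("matcher", rows, bonds)


def _decoy_geometry() -> Molecule:
    # one HBD (ammonium-like N+ –H) and one HBA (carbonyl O) ~15 Å apart:
    # no feature pair can fit any CGM pair within tolerance
    return _mol(
        "decoy-geometry",
        [("N", (0.00, 0.00, 0.00), 1),
         ("H", (-0.55, -0.80, 0.10), 0),
         ("C", (2.00, 0.30, 0.00), 0),
         ("C", (5.00, 0.50, 0.40), 0),
         ("C", (12.00, 0.40, 0.00), 0),
         ("O", (14.80, 0.30, 0.30), 0)],
        [(0, 1, 1), (0, 2, 2), (2, 3, 2), (3, 4, 2), (4, 5, 2)],
        charge=1,
    )


def _decoy_kind() -> Molecule:
    # two donors, no acceptor (protonated nitrogens are excluded as HBA)
    return _mol(
        "decoy-kind",
        [("N", (0.00, 0.00, 0.00), 1),
         ("H", (-0.60, -0.70, 0.20), 0),
         ("C", (2.50, 0.50, 0.00), 0),
         ("C", (5.00, 0.50, 0.30), 0),
         ("N", (7.50, 0.20, 0.00), 1),
         ("H", (8.10, 1.00, 0.20), 0)],
        [(0, 1, 1), (0, 2, 2), (2, 3, 2), (3, 4, 2), (4, 5, 1)],
        charge=2,
    )


def _inert() -> Molecule:
    d = 0.63
    return _mol(
        "inert",
        [("C", (0, 0, 0), 0),
         ("H", (d, d, d), 0), ("H", (-d, -d, d), 0),
         ("H", (-d, d, -d), 0), ("H", (d, -d, -d), 0)],
        [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
    )


@dataclass
class PlantedLibrary:
    molecules: list
    truth: list
    seed: int
    cgm: CGM

    def __len__(self) -> int:
        return len(self.molecules)

    def to_sdf(self) -> str:
        entries = [(m, {"truth": label, "id": m.name})
                   for m, label in zip(self.molecules, self.truth)]
        return write_sdf(entries)


def _label_counts(n: int, fractions: dict) -> dict:
    """Largest-remainder apportionment, ties broken in TRUTH_LABELS order."""
    raw = {lb: n * fractions.get(lb, 0.0) for lb in TRUTH_LABELS}
    counts = {lb: int(raw[lb]) for lb in TRUTH_LABELS}
    left = n - sum(counts.values())
    order = sorted(TRUTH_LABELS, key=lambda lb: (-(raw[lb] - counts[lb]),
                                                 TRUTH_LABELS.index(lb)))
    for lb in order[:left]:
        counts[lb] += 1
    return counts


def make_planted_library(n: int = 12, fractions: dict = None,
                         seed: int = 0, jitter: float = 0.12) -> PlantedLibrary:
    """Library of n molecules with known truth labels, deterministic from seed.

    Matchers carry features within half a tolerance radius of the CGM
    feature positions (small per-atom jitter plus a random rigid motion);
    geometry decoys have the right feature kinds at hopeless distances;
    kind decoys lack an acceptor; inert molecules have no features at all.
    """
    if n < 4:
        raise UsageError("a planted library needs n >= 4")
    fractions = dict(fractions) if fractions else dict(DEFAULT_FRACTIONS)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise UsageError("truth-label fractions must sum to 1")
    cgm = make_reference_cgm()
    counts = _label_counts(n, fractions)
    labels = [lb for lb in TRUTH_LABELS for _ in range(counts[lb])]
    rng = np.random.default_rng(seed)
    builders = {"matcher": lambda: _matcher_skeleton(cgm),
                "decoy-geometry": _decoy_geometry,
                "decoy-kind": _decoy_kind,
                "inert": _inert}
    molecules = []
    for idx, label in enumerate(labels):
        mol = builders[label]()
        coords = mol.coords
        if label == "matcher" and jitter > 0:
            # uniform per-atom displacement inside a jitter-radius ball
            vec = rng.normal(size=coords.shape)
            vec /= np.linalg.norm(vec, axis=1, keepdims=True)
            coords = coords + vec * (jitter * rng.uniform(0, 1, (len(coords), 1)) ** (1 / 3))
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        t = rng.uniform(-10.0, 10.0, size=3)
        coords = coords @ R.T + t
        mol = mol.with_coords(coords)
        mol.name = f"mol_{idx:03d}_{label}"
        molecules.append(mol)
    return PlantedLibrary(molecules, labels, seed, cgm)


# ---------------------------------------------------------------- small molecules

def make_butane_like() -> Molecule:
    """A 4-heavy-atom chain with one rotatable central bond (toy torsion fixture)."""
    return _mol(
        "butane-like",
        [("C", (0.00, 0.00, 0.00), 0),
         ("C", (1.54, 0.00, 0.00), 0),
         ("C", (2.05, 1.45, 0.00), 0),
         ("C", (3.59, 1.45, 0.00), 0)],
        [(0, 1, 1), (1, 2, 1), (2, 3, 1)],
    )


def make_rigid_ring() -> Molecule:
    """A planar aromatic six-ring (benzene-like) with no rotatable bonds."""
    rows, bonds = [], []
    for k in range(6):
        ang = np.pi / 3 * k
        rows.append(("C", (1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0), 0))
        bonds.append((k, (k + 1) % 6, 4, True))
    return _mol("ring", rows, bonds)


def make_methanol() -> Molecule:
    return _mol(
        "methanol",
        [("C", (0.00, 0.00, 0.00), 0),
         ("O", (1.43, 0.00, 0.00), 0),
         ("H", (1.78, 0.87, 0.20), 0),
         ("H", (-0.36, 1.02, 0.00), 0),
         ("H", (-0.36, -0.51, 0.89), 0),
         ("H", (-0.36, -0.51, -0.89), 0)],
        [(0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1)],
    )


# ---------------------------------------------------------------- thermochemistry

def make_thermo_fixture() -> dict:
    """Monoatomic / linear / nonlinear species plus floor-straddling modes."""
    argon = Molecule([Atom("Ar", np.zeros(3))], name="Ar")
    co2 = _mol("CO2", [("O", (0, 0, 1.16), 0), ("C", (0, 0, 0), 0),
                       ("O", (0, 0, -1.16), 0)],
               [(0, 1, 2), (1, 2, 2)])
    water = _mol("H2O", [("O", (0.0, 0.0, 0.117), 0),
                         ("H", (0.0, 0.757, -0.470), 0),
                         ("H", (0.0, -0.757, -0.470), 0)],
                 [(0, 1, 1), (0, 2, 1)])
    floppy = _mol("floppy", [("C", (0, 0, 0), 0), ("O", (1.2, 0, 0), 0),
                             ("C", (-0.8, 1.1, 0.3), 0)],
                  [(0, 1, 2), (0, 2, 1)])
    return {
        "argon": ThermoInput(argon, e_elec=0.0, freqs=FrequencySet([])),
        "co2": ThermoInput(co2, e_elec=0.0,
                           freqs=FrequencySet([667.4, 667.4, 1333.0, 2349.0]),
                           sigma=2),
        "water": ThermoInput(water, e_elec=0.0,
                             freqs=FrequencySet([1595.0, 3657.0, 3756.0]),
                             sigma=2),
        # straddles the quasi-harmonic floor, including the exact boundary
        "floppy": ThermoInput(floppy, e_elec=0.0,
                              freqs=FrequencySet([50.0, 100.0, 150.0, 800.0])),
        "ts": ThermoInput(floppy, e_elec=10.0,
                          freqs=FrequencySet([90.0, 400.0, 1200.0], n_imaginary=1),
                          is_ts=True),
    }
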