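"""Transition-state (theozyme) templates and their diversification.

A theozyme template is a pair of substrate fragments frozen at a coupling
transition-state-like geometry — a malonate-like nucleophile and a
nitroalkene-like electrophile joined by a partially formed C–C bond —
plus two catalytic-site placeholders (one H-bond-donor site, one
H-bond-acceptor site) that mark where a bifunctional catalyst's functional
groups must sit.

Diversification enumerates the combinatorial degrees of freedom of the
coupling step:

* binding mode (BMA/BMB) — which substrate each catalytic site engages;
  the two classic arrangements for bifunctional thiourea/amine catalysis,
* enantiotopic face (Re/Si) — mirror image of the electrophile approach,
  which decides the product configuration,
* rotamer about the forming C–C bond — the relative orientation of the
  two catalytic groups.

All operations are rigid and return new templates; coordinates of the
input are never mutated.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .chem import Molecule
from .errors import GeometryError, UsageError
from .geometry import reflect_across_plane, rotation_about_axis

BINDING_MODES = ("BMA", "BMB")
FACES = ("Re", "Si")
NUCLEOPHILE = "nucleophile"
ELECTROPHILE = "electrophile"


@dataclass
class AnchorSpec:
    """How a catalytic site attaches to one substrate fragment.

    contact_atoms are the two H-bond contact atoms on that fragment (e.g.
    the two nitro oxygens); center_atom gives the outward direction (site
    positions point away from it); standoff is the contact distance in Å.
    """

    contact_atoms: tuple[int, int]
    center_atom: int
    standoff: float = 2.0


@dataclass
class CatalyticSite:
    """A placeholder for one catalyst functional group.

    double_contact sites engage both anchor contact atoms (e.g. a
    (thio)urea donating two H-bonds to both nitro oxygens, or a malonate
    accepting at both carbonyls); single-contact sites engage the contact
    midpoint. positions/direction are derived quantities, recomputed from
    the anchor geometry after every rigid operation.
    """

    kind: str  # "HBD" | "HBA"
    double_contact: bool = False
    positions: list = field(default_factory=list)
    direction: Optional[np.ndarray] = None

    @property
    def position(self) -> np.ndarray:
        """Representative (mean) site position."""
        return np.mean(np.asarray(self.positions), axis=0)


@dataclass
class TSTemplate:
    nucleophile: Molecule
    electrophile: Molecule
    sites: dict  # {"HBD": CatalyticSite, "HBA": CatalyticSite}
    anchors: dict  # {NUCLEOPHILE: AnchorSpec, ELECTROPHILE: AnchorSpec}
    forming_bond: tuple  # (nucleophile atom index, electrophile atom index)
    binding_mode: str = "BMA"
    face: str = "Re"
    rotamer_deg: float = 0.0

    def __post_init__(self) -> None:
        i, j = self.forming_bond
        if not (0 <= i < len(self.nucleophile)):
            raise UsageError("forming-bond nucleophile atom index out of range")
        if not (0 <= j < len(self.electrophile)):
            raise UsageError("forming-bond electrophile atom index out of range")
        if self.binding_mode not in BINDING_MODES:
            raise UsageError(f"unknown binding mode: {self.binding_mode!r}")
        if self.face not in FACES:
            raise UsageError(f"unknown face label: {self.face!r}")
        self.rotamer_deg = float(self.rotamer_deg) % 360.0
        _update_sites(self)

    # -- derived geometry -------------------------------------------------

    @property
    def forming_bond_length(self) -> float:
        i, j = self.forming_bond
        return float(np.linalg.norm(
            self.nucleophile.atoms[i].position - self.electrophile.atoms[j].position))

    def site_fragment(self, kind: str) -> str:
        """Which fragment the given site anchors to under the current mode."""
        if kind not in ("HBD", "HBA"):
            raise UsageError(f"unknown site kind: {kind!r}")
        if self.binding_mode == "BMA":
            return ELECTROPHILE if kind == "HBD" else NUCLEOPHILE
        return NUCLEOPHILE if kind == "HBD" else ELECTROPHILE

    def fragment(self, which: str) -> Molecule:
        return self.nucleophile if which == NUCLEOPHILE else self.electrophile

    def substrate_atoms(self):
        """All substrate atoms (both fragments), nucleophile first."""
        return list(self.nucleophile.atoms) + list(self.electrophile.atoms)


def _update_sites(t: TSTemplate) -> None:
    """Recompute site positions from the anchoring rule.

    position_k = contact_k + standoff * unit(contact_k - center) for a
    double-contact site; the single-contact variant uses the contact
    midpoint. The direction vector points from the site toward its
    contacts (i.e. along the would-be H-bond).
    """
    for kind, site in t.sites.items():
        frag_name = t.site_fragment(kind)
        anchor = t.anchors[frag_name]
        coords = t.fragment(frag_name).coords
        c1 = coords[anchor.contact_atoms[0]]
        c2 = coords[anchor.contact_atoms[1]]
        center = coords[anchor.center_atom]
        if site.double_contact:
            raw = [c1, c2]
        else:
            raw = [(c1 + c2) / 2.0]
        positions = []
        for c in raw:
            out = c - center
            n = np.linalg.norm(out)
            if n < 1e-9:
                raise GeometryError("anchor contact coincides with its center atom")
            positions.append(c + anchor.standoff * out / n)
        site.positions = positions
        contact_centroid = np.mean(np.asarray(raw), axis=0)
        d = contact_centroid - np.mean(np.asarray(positions), axis=0)
        site.direction = d / np.linalg.norm(d)


def _clone(t: TSTemplate) -> TSTemplate:
    return copy.deepcopy(t)


def apply_binding_mode(t: TSTemplate, mode: str) -> TSTemplate:
    """Return the template with the given binding mode.

    BMA anchors the HBD site to the electrophile's nitro group and the HBA
    site to the nucleophile; BMB exchanges the assignments. Site positions
    are recomputed on the new fragment with the same anchoring rule, so
    applying BMB and then BMA restores the original sites exactly.
    """
    if mode not in BINDING_MODES:
        raise UsageError(f"unknown binding mode: {mode!r} (expected BMA or BMB)")
    new = _clone(t)
    new.binding_mode = mode
    _update_sites(new)
    return new


def mirror_enantioface(t: TSTemplate) -> TSTemplate:
    """Reflect the electrophile to expose the opposite enantiotopic face.

    The mirror plane contains the forming-bond axis and the electrophile's
    anchor center atom (the nitro nitrogen), so the forming bond itself and
    the nitro attachment stay in the plane while the electrophile's
    chirality of approach inverts. Face label toggles Re <-> Si.
    """
    new = _clone(t)
    i, j = t.forming_bond
    a = t.nucleophile.atoms[i].position
    b = t.electrophile.atoms[j].position
    c = t.electrophile.coords[t.anchors[ELECTROPHILE].center_atom]
    normal = np.cross(b - a, c - a)
    if np.linalg.norm(normal) < 1e-8:
        raise GeometryError(
            "forming-bond axis and electrophile reference atom are collinear; "
            "mirror plane is undefined")
    reflected = reflect_across_plane(t.electrophile.coords, b, normal)
    new.electrophile = t.electrophile.with_coords(reflected)
    new.face = "Si" if t.face == "Re" else "Re"
    _update_sites(new)
    return new


def rotate_forming_bond(t: TSTemplate, angle_deg: float) -> TSTemplate:
    """Rigidly rotate the nucleophile fragment about the forming C–C axis.

    Catalytic sites anchored on the nucleophile follow (they are recomputed
    from the rotated anchor atoms). The forming-bond length is invariant
    because the nucleophile's forming atom lies on the axis.
    """
    if not np.isfinite(angle_deg):
        raise UsageError("rotation angle must be finite")
    new = _clone(t)
    i, j = t.forming_bond
    a = t.nucleophile.atoms[i].position
    b = t.electrophile.atoms[j].position
    axis = b - a
    if np.linalg.norm(axis) < 1e-9:
        raise GeometryError("forming-bond atoms coincide; rotation axis undefined")
    R, trans = rotation_about_axis(a, axis, angle_deg)
    rotated = t.nucleophile.coords @ R.T + trans
    new.nucleophile = t.nucleophile.with_coords(rotated)
    new.rotamer_deg = (t.rotamer_deg + angle_deg) % 360.0
    _update_sites(new)
    return new


@dataclass
class VariantSet:
    variants: list
    provenance: dict

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def enumerate_variants(t: TSTemplate, rotamer_step_deg: float = 60.0) -> VariantSet:
    """Enumerate the full diversification of a template.

    Cartesian product of binding modes {BMA, BMB} x faces {Re, Si} x
    rotamers {0, step, ..., 360 - step}, in that (mode, face, angle
    ascending) order. With the default 60° step this yields
    2 x 2 x 6 = 24 templates per model.
    """
    if rotamer_step_deg <= 0 or abs(360.0 / rotamer_step_deg
                                    - round(360.0 / rotamer_step_deg)) > 1e-9:
        raise UsageError("rotamer step must be a positive divisor of 360")
    n_rot = int(round(360.0 / rotamer_step_deg))
    variants = []
    for mode in BINDING_MODES:
        tm = apply_binding_mode(t, mode)
        for face in FACES:
            tf = tm if tm.face == face else mirror_enantioface(tm)
            for k in range(n_rot):
                variants.append(rotate_forming_bond(tf, k * rotamer_step_deg))
    provenance = {
        "binding_modes": list(BINDING_MODES),
        "faces": list(FACES),
        "rotamer_step_deg": rotamer_step_deg,
        "n_rotamers": n_rot,
        "source_mode": t.binding_mode,
        "source_face": t.face,
    }
    return VariantSet(variants, provenance)


# ---------------------------------------------------------------- serialization

def template_to_dict(t: TSTemplate) -> dict:
    from .io import write_xyz

    return {
        "binding_mode": t.binding_mode,
        "face": t.face,
        "rotamer_deg": t.rotamer_deg,
        "forming_bond": list(t.forming_bond),
        "nucleophile_xyz": write_xyz(t.nucleophile),
        "electrophile_xyz": write_xyz(t.electrophile),
        "anchors": {
            name: {"contact_atoms": list(a.contact_atoms),
                   "center_atom": a.center_atom,
                   "standoff": a.standoff}
            for name, a in t.anchors.items()
        },
        "sites": {
            kind: {"double_contact": s.double_contact}
            for kind, s in t.sites.items()
        },
    }


def template_from_dict(d: dict) -> TSTemplate:
    from .io import read_xyz

    anchors = {
        name: AnchorSpec(tuple(v["contact_atoms"]), v["center_atom"],
                         v.get("standoff", 2.0))
        for name, v in d["anchors"].items()
    }
    sites = {
        kind: CatalyticSite(kind=kind, double_contact=v.get("double_contact", False))
        for kind, v in d["sites"].items()
    }
    return TSTemplate(
        nucleophile=read_xyz(d["nucleophile_xyz"])[0],
        electrophile=read_xyz(d["electrophile_xyz"])[0],
        sites=sites,
        anchors=anchors,
        forming_bond=tuple(d["forming_bond"]),
        binding_mode=d.get("binding_mode", "BMA"),
        face=d.get("face", "Re"),
        rotamer_deg=d.get("rotamer_deg", 0.0),
    )
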