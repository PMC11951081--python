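"""Readers and writers for XYZ (multi-frame) and SDF V2000.

SDF parsing and molblock generation go through RDKit (without
sanitization, so idealized fixture molecules with unusual valences pass
through unchanged); SD data fields are handled at the record level so that
parse errors can name the offending record and V3000 records are rejected
loudly rather than half-read.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers mol ops)
from rdkit.Geometry import Point3D

from . import periodic
from .chem import Atom, Bond, Conformer, Molecule
from .errors import ParseError, UnsupportedFormatError, UsageError

# ---------------------------------------------------------------- XYZ

def read_xyz(text: str) -> list[Molecule]:
    """Parse (possibly multi-frame) XYZ text into one Molecule per frame."""
    lines = text.splitlines()
    mols: list[Molecule] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"line {pos + 1}: expected an atom count") from None
        if natoms < 1:
            raise ParseError(f"line {pos + 1}: atom count must be positive")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        atoms = []
        for k in range(natoms):
            ln = pos + 2 + k
            if ln >= len(lines):
                raise ParseError(
                    f"line {ln + 1}: frame declares {natoms} atoms but input ended")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'element x y z'")
            sym = parts[0]
            if not periodic.is_known_element(sym):
                raise ParseError(f"line {ln + 1}: unknown element {sym!r}")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {ln + 1}: non-numeric coordinate") from None
            atoms.append(Atom(sym, np.array(xyz)))
        mols.append(Molecule(atoms, name=comment.strip()))
        pos += 2 + natoms
    if not mols:
        raise ParseError("no XYZ frames found")
    return mols


def write_xyz(mol: Molecule, comment: Optional[str] = None) -> str:
    """Serialize one Molecule as XYZ text with 6-decimal coordinates."""
    if len(mol) == 0:
        raise UsageError("cannot write an empty molecule")
    coords = mol.coords
    if not np.all(np.isfinite(coords)):
        raise UsageError("cannot write non-finite coordinates")
    head = comment if comment is not None else mol.name
    rows = [str(len(mol)), head]
    for a in mol.atoms:
        x, y, z = a.position
        rows.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(rows) + "\n"


def write_xyz_frames(mols: Sequence[Molecule]) -> str:
    """Multi-frame XYZ: concatenation of single-frame blocks."""
    return "".join(write_xyz(m) for m in mols)


# ---------------------------------------------------------------- SDF V2000

_BOND_ORDER_FROM_RD = {
    Chem.BondType.SINGLE: (1, False),
    Chem.BondType.DOUBLE: (2, False),
    Chem.BondType.TRIPLE: (3, False),
    Chem.BondType.AROMATIC: (4, True),
}
_RD_FROM_BOND_ORDER = {
    (1, False): Chem.BondType.SINGLE,
    (2, False): Chem.BondType.DOUBLE,
    (3, False): Chem.BondType.TRIPLE,
    (4, True): Chem.BondType.AROMATIC,
}


def _split_sdf_records(text: str) -> list[str]:
    records, cur = [], []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append("\n".join(cur) + "\n")
            cur = []
        else:
            cur.append(line)
    if any(ln.strip() for ln in cur):
        records.append("\n".join(cur) + "\n")
    return records


def _parse_data_fields(record: str) -> dict[str, str]:
    lines = record.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("M  END")) + 1
    except StopIteration:
        return {}
    props: dict[str, str] = {}
    i = start
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("> "):
            tag = ln.split("<", 1)[-1].rsplit(">", 1)[0] if "<" in ln else ln[2:].strip()
            vals = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                vals.append(lines[i])
                i += 1
            props[tag] = "\n".join(vals)
        i += 1
    return props


def read_sdf(text: str) -> list[Molecule]:
    """Parse a (multi-record) SDF V2000 string.

    Bond order 4 is mapped to an aromatic flag. SD data fields named
    'energy' and 'id' are not interpreted here; use read_sdf_records for
    property access.
    """
    return [m for m, _ in read_sdf_records(text)]


def read_sdf_records(text: str) -> list[tuple[Molecule, dict[str, str]]]:
    """Like read_sdf but also returns each record's SD data fields."""
    records = _split_sdf_records(text)
    if not records:
        raise ParseError("no SDF records found")
    out = []
    for ridx, rec in enumerate(records, start=1):
        lines = rec.splitlines()
        if len(lines) < 4:
            raise ParseError(f"record {ridx}: truncated (no counts line)")
        counts = lines[3]
        if "V3000" in counts:
            raise UnsupportedFormatError(
                f"record {ridx}: SDF V3000 dialect is not supported (V2000 only)")
        try:
            natoms = int(counts[0:3])
            nbonds = int(counts[3:6])
        except ValueError:
            raise ParseError(f"record {ridx}: malformed counts line") from None
        if natoms < 1:
            raise ParseError(f"record {ridx}: counts line declares {natoms} atoms")
        rd = Chem.MolFromMolBlock(rec, sanitize=False, removeHs=False)
        if rd is None:
            raise ParseError(f"record {ridx}: RDKit could not parse the molblock")
        if rd.GetNumAtoms() != natoms:
            raise ParseError(
                f"record {ridx}: counts line declares {natoms} atoms, "
                f"parsed {rd.GetNumAtoms()}")
        conf = rd.GetConformer()
        atoms = []
        for a in rd.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(Atom(a.GetSymbol(), np.array([p.x, p.y, p.z]),
                              formal_charge=a.GetFormalCharge()))
        bonds = []
        for b in rd.GetBonds():
            order, arom = _BOND_ORDER_FROM_RD.get(b.GetBondType(), (1, False))
            bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, arom))
        if len(bonds) != nbonds:
            raise ParseError(f"record {ridx}: bond block truncated")
        name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
        charge = sum(a.GetFormalCharge() for a in rd.GetAtoms())
        mol = Molecule(atoms, bonds, charge=charge, name=name)
        out.append((mol, _parse_data_fields(rec)))
    return out


def _to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in mol.bonds:
        bt = _RD_FROM_BOND_ORDER.get((b.order, b.aromatic))
        if bt is None:
            bt = Chem.BondType.AROMATIC if b.aromatic else Chem.BondType.SINGLE
        rw.AddBond(b.i, b.j, bt)
        if b.aromatic:
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
    conf = Chem.Conformer(len(mol))
    for k, a in enumerate(mol.atoms):
        if not np.all(np.isfinite(a.position)):
            raise UsageError("cannot write non-finite coordinates")
        conf.SetAtomPosition(k, Point3D(*map(float, a.position)))
    m = rw.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    m.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(m)
    return m


def write_sdf(entries: Sequence[tuple[Molecule, dict[str, str]]]) -> str:
    """Serialize molecules (with SD data fields) as a multi-record SDF V2000."""
    if not entries:
        raise UsageError("cannot write an empty SDF")
    chunks = []
    for mol, props in entries:
        if len(mol) == 0:
            raise UsageError("cannot write an empty molecule")
        block = Chem.MolToMolBlock(_to_rdkit(mol), kekulize=False)
        body = block.rstrip("\n")
        for tag in sorted(props):
            body += f"\n> <{tag}>\n{props[tag]}\n"
        chunks.append(body + "\n$$$$\n")
    return "".join(chunks)


def write_sdf_conformers(conformers: Sequence[Conformer]) -> str:
    """SDF export of a conformer list, with energy and id as data fields."""
    entries = []
    for c in conformers:
        props = {"id": c.id}
        if c.energy is not None:
            props["energy"] = f"{c.energy:.6f}"
        entries.append((c.as_molecule(), props))
    return write_sdf(entries)
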