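"""Molecular model, XYZ/SDF round-trips, superposition and RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from cipoc.chem import Atom, Bond, Conformer, Molecule
from cipoc.errors import ParseError, UnsupportedFormatError, UsageError
from cipoc.fixtures import make_methanol, make_rigid_ring
from cipoc.geometry import rmsd_heavy, superpose
from cipoc.io import read_sdf, read_xyz, write_sdf, write_xyz

from oracles import brute_force_superpose

WATER_XYZ = "3\nwater\nO 0.0 0.0 0.117\nH 0.0 0.757 -0.470\nH 0.0 -0.757 -0.470\n"


class TestModel:
    def test_unknown_element_rejected(self):
        with pytest.raises(UsageError):
            Atom("Xq", np.zeros(3))

    def test_nonfinite_position_rejected(self):
        with pytest.raises(UsageError):
            Atom("C", np.array([0.0, np.nan, 0.0]))

    def test_mass_filled_from_table(self):
        assert Atom("C", np.zeros(3)).mass == pytest.approx(12.011)

    @pytest.mark.parametrize("bonds", [[(0, 5, 1)], [(1, 1, 1)]])
    def test_bad_bonds_rejected(self, bonds):
        atoms = [Atom("C", np.zeros(3)), Atom("C", np.ones(3))]
        with pytest.raises(UsageError):
            Molecule(atoms, [Bond(*b) for b in bonds])

    def test_conformer_shape_checked(self):
        mol = make_methanol()
        with pytest.raises(UsageError):
            Conformer(mol, np.zeros((2, 3)))


class TestXYZ:
    def test_water_frame(self):
        mol = read_xyz(WATER_XYZ)[0]
        assert len(mol) == 3
        assert mol.atoms[0].element == "O"
        assert mol.bonds == []

    def test_round_trip_six_decimals(self):
        mol = read_xyz(WATER_XYZ)[0]
        again = read_xyz(write_xyz(mol))[0]
        assert np.abs(mol.coords - again.coords).max() < 5e-7

    def test_single_atom_format(self):
        mol = Molecule([Atom("Ar", np.zeros(3))])
        assert write_xyz(mol, comment="") == "1\n\nAr 0.000000 0.000000 0.000000\n"

    def test_count_mismatch_names_line(self):
        with pytest.raises(ParseError, match="line"):
            read_xyz("4\n\nO 0 0 0\nH 0 0 1\nH 0 1 0\n")

    def test_unknown_element_is_parse_error(self):
        with pytest.raises(ParseError, match="Zz"):
            read_xyz("1\n\nZz 0 0 0\n")

    def test_multi_frame(self):
        assert len(read_xyz(WATER_XYZ + WATER_XYZ)) == 2

    def test_empty_molecule_write_rejected(self):
        with pytest.raises(UsageError):
            write_xyz(Molecule([]))

    def test_nan_coordinate_write_rejected(self):
        mol = read_xyz(WATER_XYZ)[0]
        mol.atoms[0].position[0] = np.nan
        with pytest.raises(UsageError):
            write_xyz(mol)


class TestSDF:
    def test_benzene_aromatic_bonds(self):
        ring = make_rigid_ring()
        parsed = read_sdf(write_sdf([(ring, {})]))[0]
        assert sum(b.aromatic for b in parsed.bonds) == 6
        assert all(b.order == 4 for b in parsed.bonds if b.aromatic)

    def test_multi_record(self):
        ring, me = make_rigid_ring(), make_methanol()
        mols = read_sdf(write_sdf([(ring, {}), (me, {})]))
        assert len(mols) == 2
        assert [len(m) for m in mols] == [6, 6]

    def test_round_trip_coordinates(self):
        me = make_methanol()
        again = read_sdf(write_sdf([(me, {})]))[0]
        # molblock carries 4 decimals
        assert np.abs(me.coords - again.coords).max() < 5e-4
        assert [b[:2] for b in again.bonds] == [b[:2] for b in me.bonds]

    def test_v3000_rejected(self):
        block = ("m\n\n\n  0  0  0  0  0  0  0  0  0  0999 V3000\n"
                 "M  END\n$$$$\n")
        with pytest.raises(UnsupportedFormatError):
            read_sdf(block)

    def test_zero_atoms_rejected(self):
        block = ("m\n\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n$$$$\n")
        with pytest.raises(ParseError):
            read_sdf(block)

    def test_truncated_record_rejected(self):
        good = write_sdf([(make_methanol(), {})])
        truncated = "\n".join(good.splitlines()[:6]) + "\n$$$$\n"
        with pytest.raises(ParseError):
            read_sdf(truncated)


class TestSuperpose:
    def test_identity(self, rng):
        P = rng.normal(size=(5, 3))
        R, t, rmsd = superpose(P, P)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        P = rng.normal(size=(5, 3))
        shift = np.array([1.0, 2.0, 3.0])
        R, t, rmsd = superpose(P, P + shift)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, shift, atol=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        _, _, expected = brute_force_superpose(P, Q)
        assert superpose(P, Q).rmsd == pytest.approx(expected, abs=1e-3)

    def test_proper_rotation_even_for_mirrored_input(self, rng):
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflection: a proper rotation cannot reach rmsd 0
        R, _, rmsd = superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_size_mismatch(self):
        with pytest.raises(UsageError):
            superpose(np.zeros((3, 3)), np.zeros((4, 3)))

    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        base = superpose(P, Q).rmsd
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        t = rng.normal(size=3)
        moved = superpose(P @ R.T + t, Q @ R.T + t).rmsd
        assert abs(base - moved) < 1e-9


def _chain_conformer(coords):
    mol = Molecule([Atom("C", c) for c in coords])
    return Conformer(mol, np.asarray(coords, float))


class TestRmsdHeavy:
    def test_identical_is_zero(self, rng):
        c = _chain_conformer(rng.normal(size=(4, 3)))
        assert rmsd_heavy(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copy_aligns_to_zero(self, rng):
        coords = rng.normal(size=(5, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        a = _chain_conformer(coords)
        b = Conformer(a.molecule, coords @ R.T + np.array([3.0, -1.0, 0.5]))
        assert rmsd_heavy(a, b, align=True) <= 1e-6
        assert rmsd_heavy(a, b, align=False) > 0.1

    def test_single_displaced_atom_unaligned(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [6, 0, 0], [9, 0, 0]], float)
        a = _chain_conformer(coords)
        moved = coords.copy()
        moved[0, 1] += 1.0
        b = Conformer(a.molecule, moved)
        assert rmsd_heavy(a, b, align=False) == pytest.approx(0.5)

    def test_hydrogens_excluded(self):
        mol = Molecule([Atom("C", (0, 0, 0)), Atom("H", (1, 0, 0))])
        a = Conformer(mol, mol.coords)
        moved = mol.coords.copy()
        moved[1] += 5.0
        b = Conformer(mol, moved)
        assert rmsd_heavy(a, b, align=False) == pytest.approx(0.0, abs=1e-12)

    def test_atom_count_mismatch(self, rng):
        a = _chain_conformer(rng.normal(size=(4, 3)))
        b = _chain_conformer(rng.normal(size=(5, 3)))
        with pytest.raises(UsageError):
            rmsd_heavy(a, b)

    @given(st.integers(0, 10_000))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        mol = Molecule([Atom("C", c) for c in rng.normal(size=(5, 3))])
        a, b, c = (Conformer(mol, rng.normal(size=(5, 3), scale=2.0))
                   for _ in range(3))
        dab, dba = rmsd_heavy(a, b), rmsd_heavy(b, a)
        assert dab == pytest.approx(dba, abs=1e-9)
        dac, dcb = rmsd_heavy(a, c), rmsd_heavy(c, b)
        assert dab <= dac + dcb + 1e-9
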