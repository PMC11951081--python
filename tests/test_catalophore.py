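"""CGM construction, feature perception, partial 3D matching, hit ranking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cipoc.catalophore import (CGM, ExclusionSphere, Feature, build_cgm,
                               cgm_from_dict, cgm_to_dict, match,
                               perceive_features, rank_hits)
from cipoc.chem import Atom, Conformer, Molecule
from cipoc.errors import UsageError
from cipoc.fixtures import (make_methanol, make_planted_library,
                            make_reference_template, make_rigid_ring, _inert)

from oracles import brute_force_match


class TestBuildCGM:
    def test_double_contact_acceptor_gives_three_features(self):
        cgm = build_cgm(make_reference_template(double_hba=True))
        kinds = sorted(f.kind for f in cgm.features)
        assert kinds == ["HBA", "HBA", "HBD"]

    def test_single_contact_acceptor_gives_two_features(self):
        cgm = build_cgm(make_reference_template(double_hba=False))
        assert sorted(f.kind for f in cgm.features) == ["HBA", "HBD"]

    def test_exclusions_cover_substrate_heavy_atoms(self):
        t = make_reference_template()
        cgm = build_cgm(t)
        n_heavy = sum(1 for a in t.substrate_atoms() if a.is_heavy)
        assert len(cgm.exclusions) == n_heavy
        assert all(s.radius > 0 for s in cgm.exclusions)

    def test_tolerance_override(self):
        cgm = build_cgm(make_reference_template(), tolerances={"HBD": 0.5})
        hbd = next(f for f in cgm.features if f.kind == "HBD")
        hba = next(f for f in cgm.features if f.kind == "HBA")
        assert hbd.tolerance == 0.5
        assert hba.tolerance == 1.0

    def test_yaml_dict_round_trip(self, reference_cgm):
        back = cgm_from_dict(cgm_to_dict(reference_cgm))
        assert len(back.features) == len(reference_cgm.features)
        assert back.min_match == reference_cgm.min_match
        for a, b in zip(back.features, reference_cgm.features):
            assert a.kind == b.kind
            assert np.allclose(a.position, b.position)


class TestPerceiveFeatures:
    def test_methanol_one_donor_one_acceptor(self):
        me = make_methanol()
        feats = perceive_features(Conformer(me, me.coords))
        kinds = sorted(f.kind for f in feats)
        assert kinds == ["HBA", "HBD"]
        hbd = next(f for f in feats if f.kind == "HBD")
        # HBD sits on the hydroxyl hydrogen, direction along O->H
        assert np.allclose(hbd.position, me.coords[2])
        assert np.dot(hbd.direction, me.coords[2] - me.coords[1]) > 0.99 * np.linalg.norm(
            me.coords[2] - me.coords[1])

    def test_benzene_single_centroid(self):
        ring = make_rigid_ring()
        feats = perceive_features(Conformer(ring, ring.coords))
        assert [f.kind for f in feats] == ["AromaticCentroid"]
        assert np.allclose(feats[0].position, ring.coords.mean(axis=0), atol=1e-9)

    def test_methane_has_no_features(self):
        mol = _inert()
        assert perceive_features(Conformer(mol, mol.coords)) == []

    def test_positively_charged_nitrogen_not_acceptor(self):
        mol = Molecule(
            [Atom("N", (0, 0, 0), formal_charge=1), Atom("H", (1, 0, 0))],
            bonds=[(0, 1, 1, False)], charge=1)
        kinds = [f.kind for f in perceive_features(Conformer(mol, mol.coords))]
        assert kinds == ["HBD"]

    def test_requires_bonds(self):
        mol = Molecule([Atom("O", (0, 0, 0))])
        with pytest.raises(UsageError):
            perceive_features(Conformer(mol, mol.coords))


def _feature_cloud_conformer(positions):
    """Inert carbon scaffold placed far away; features supplied explicitly."""
    mol = Molecule([Atom("C", (50.0, 50.0, 50.0)), Atom("C", (52.0, 50.0, 50.0))],
                   bonds=[(0, 1, 1, False)])
    return Conformer(mol, mol.coords)


class TestMatch:
    def test_exact_coincidence_full_match(self, reference_cgm):
        conf = _feature_cloud_conformer(None)
        feats = [Feature(f.kind, f.position.copy()) for f in reference_cgm.features]
        results = match(reference_cgm, conf, features=feats)
        assert results
        assert results[0].n_matched == len(reference_cgm.features)
        assert results[0].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_single_feature_below_min_match(self, reference_cgm):
        conf = _feature_cloud_conformer(None)
        feats = [Feature("HBD", reference_cgm.features[0].position.copy())]
        assert match(reference_cgm, conf, features=feats) == []

    def test_partial_two_of_three_matches_brute_force(self, reference_cgm):
        """Two features displaced 0.3 Å from their CGM positions, third
        absent: one maximal 2-feature hit whose RMSD agrees with the
        exhaustive correspondence + grid-rotation oracle."""
        hbd, hba1, _ = reference_cgm.features
        feats = [
            Feature("HBD", hbd.position + np.array([0.3, 0.0, 0.0])),
            Feature("HBA", hba1.position + np.array([0.0, -0.3, 0.0])),
        ]
        conf = _feature_cloud_conformer(None)
        results = match(reference_cgm, conf, features=feats)
        assert results
        assert results[0].n_matched == 2
        oracle = brute_force_match(reference_cgm, feats, np.empty((0, 3)))
        assert oracle
        assert results[0].rmsd == pytest.approx(min(oracle.values()), abs=1e-3)

    def test_strict_partial_policy_excludes_full(self, reference_cgm):
        strict = CGM(reference_cgm.features, reference_cgm.exclusions,
                     min_match=2, allow_full=False)
        conf = _feature_cloud_conformer(None)
        feats = [Feature(f.kind, f.position.copy()) for f in reference_cgm.features]
        results = match(strict, conf, features=feats)
        assert results
        assert max(r.n_matched for r in results) == len(reference_cgm.features) - 1

    def test_exclusion_sphere_vetoes(self):
        cgm = CGM(
            features=[Feature("HBD", (0, 0, 0), tolerance=1.0),
                      Feature("HBA", (4, 0, 0), tolerance=1.0)],
            exclusions=[ExclusionSphere((2.0, 0.0, 0.0), 1.0)])
        mol = Molecule(
            [Atom("O", (0, 0, 0)), Atom("H", (0.2, 0, 0)),
             Atom("N", (4, 0, 0)), Atom("C", (2.0, 0.3, 0.0))],
            bonds=[(0, 1, 1, False), (0, 3, 1, False), (2, 3, 1, False)])
        conf = Conformer(mol, mol.coords)
        # the carbon sits inside the exclusion sphere at every fit
        assert match(cgm, conf) == []

    def test_rigid_motion_invariance(self, reference_cgm, rng):
        lib = make_planted_library(n=4, fractions={"matcher": 1.0}, seed=2)
        mol = lib.molecules[0]
        base = match(reference_cgm, Conformer(mol, mol.coords))
        R = Rotation.from_euler("zyx", [0.7, -0.4, 2.2]).as_matrix()
        t = np.array([5.0, -3.0, 1.5])
        moved = match(reference_cgm, Conformer(mol, mol.coords @ R.T + t))
        assert [r.n_matched for r in base] == [r.n_matched for r in moved]
        for a, b in zip(base, moved):
            assert a.rmsd == pytest.approx(b.rmsd, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_brute_force_on_random_clouds(self, seed, reference_cgm):
        """Acceptance set and best RMSD match exhaustive enumeration for
        random feature clouds around the 3-feature CGM."""
        rng = np.random.default_rng(seed)
        feats = []
        for f in reference_cgm.features:
            feats.append(Feature(f.kind, f.position + rng.normal(scale=0.5, size=3)))
        feats.append(Feature("HBA", rng.uniform(-6, 6, 3)))
        conf = _feature_cloud_conformer(None)
        results = match(reference_cgm, conf, features=feats)
        got = {frozenset(r.correspondence.items()): r.rmsd for r in results}
        oracle = brute_force_match(reference_cgm, feats,
                                   conf.coordinates[conf.molecule.heavy_indices])
        assert set(got) == set(oracle)
        for key in got:
            assert got[key] == pytest.approx(oracle[key], abs=1e-3)

    def test_every_result_satisfies_min_match(self, reference_cgm, rng):
        feats = [Feature(f.kind, f.position + rng.normal(scale=0.3, size=3))
                 for f in reference_cgm.features]
        conf = _feature_cloud_conformer(None)
        for r in match(reference_cgm, conf, features=feats):
            assert r.n_matched >= 2


class TestRankHits:
    def test_more_matches_beat_lower_rmsd(self):
        df = rank_hits([
            {"catalyst_id": "a", "conformer_id": "c0", "n_matched": 2,
             "rmsd": 0.1, "energy": 0.0},
            {"catalyst_id": "b", "conformer_id": "c0", "n_matched": 3,
             "rmsd": 0.4, "energy": 0.0},
        ])
        assert list(df["catalyst_id"]) == ["b", "a"]
        assert list(df["rank"]) == [1, 2]

    def test_rmsd_breaks_score_tie(self):
        df = rank_hits([
            {"catalyst_id": "a", "conformer_id": "c0", "n_matched": 2,
             "rmsd": 0.5, "energy": 0.0},
            {"catalyst_id": "b", "conformer_id": "c0", "n_matched": 2,
             "rmsd": 0.2, "energy": 0.0},
        ])
        assert list(df["catalyst_id"]) == ["b", "a"]

    def test_full_tie_preserves_input_order(self):
        rows = [{"catalyst_id": f"m{i}", "conformer_id": "c0", "n_matched": 2,
                 "rmsd": 0.3, "energy": 1.0} for i in range(4)]
        df = rank_hits(rows)
        assert list(df["catalyst_id"]) == ["m0", "m1", "m2", "m3"]

    def test_empty_input_gives_empty_table(self):
        assert rank_hits([]).empty
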