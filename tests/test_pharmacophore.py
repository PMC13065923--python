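import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from scaffenum import (
    FeatureType,
    Pose,
    match_hypothesis,
    perceive_features,
    point_matched,
)
from scaffenum.pharmacophore import PharmacophoreHypothesis, PharmacophorePoint


def embedded_pose(smiles: str, seed: int = 7) -> Pose:
    mol = Chem.MolFromSmiles(smiles)
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return Pose(structure_id=smiles, mol=mol)


def types_of(features):
    return {f.ptype for f in features}


class TestPerception:
    def test_methanol_donor_acceptor_on_oxygen(self):
        pose = embedded_pose("CO")
        feats = perceive_features(pose)
        o_idx = next(a.GetIdx() for a in pose.mol.GetAtoms() if a.GetAtomicNum() == 8)
        hbd = [f for f in feats if f.ptype is FeatureType.HBD]
        hba = [f for f in feats if f.ptype is FeatureType.HBA]
        assert len(hbd) == 1 and hbd[0].atom_indices == {o_idx}
        assert len(hba) == 1 and hba[0].atom_indices == {o_idx}

    def test_benzene_aromatic_centroid_and_ring_hydrophobe(self):
        pose = embedded_pose("c1ccccc1")
        feats = perceive_features(pose)
        arom = [f for f in feats if f.ptype is FeatureType.AROM]
        hyd = [f for f in feats if f.ptype is FeatureType.HYD]
        assert len(arom) == 1 and len(arom[0].atom_indices) == 6
        assert np.allclose(arom[0].centroid, pose.coords.mean(axis=0), atol=1e-6)
        assert len(hyd) == 1 and hyd[0].atom_indices == arom[0].atom_indices
        assert not types_of(feats) & {FeatureType.HBD, FeatureType.HBA}

    def test_butane_hydrophobic_only(self):
        pose = embedded_pose("CCCC")
        feats = perceive_features(pose)
        assert types_of(feats) == {FeatureType.HYD}

    def test_centroid_is_unweighted_member_mean(self):
        pose = embedded_pose("CCCC")
        (hyd,) = perceive_features(pose)
        assert np.allclose(hyd.centroid, pose.coords[sorted(hyd.atom_indices)].mean(axis=0))

    def test_charged_atoms_yield_pos_neg(self):
        pose = embedded_pose("C[N+](C)(C)C")
        assert FeatureType.POS in types_of(perceive_features(pose))
        pose = embedded_pose("CC(=O)[O-]")
        assert FeatureType.NEG in types_of(perceive_features(pose))

    def test_empty_definition_set_fatal(self):
        with pytest.raises(ValueError):
            perceive_features(embedded_pose("CCO"), definitions={})


class TestPointMatched:
    def _feature(self, centroid, ptype=FeatureType.HYD, atoms=(0,)):
        from scaffenum.pharmacophore import FeatureInstance
        return FeatureInstance(ptype, frozenset(atoms), np.asarray(centroid, float))

    def test_zero_distance_matches(self):
        f = self._feature([1.0, 2.0, 3.0])
        p = PharmacophorePoint(FeatureType.HYD, np.array([1.0, 2.0, 3.0]), 1.0, key=True)
        ok, best, d = point_matched([f], p)
        assert ok and best is f and d == 0.0

    def test_boundary_distance_inclusive(self):
        f = self._feature([1.0, 0.0, 0.0])
        p = PharmacophorePoint(FeatureType.HYD, np.zeros(3), 1.0, key=True)
        ok, _, d = point_matched([f], p)
        assert ok and d == pytest.approx(1.0)

    def test_beyond_radius_not_matched(self):
        f = self._feature([1.0 + 1e-6, 0.0, 0.0])
        p = PharmacophorePoint(FeatureType.HYD, np.zeros(3), 1.0, key=True)
        ok, _, _ = point_matched([f], p)
        assert not ok

    def test_type_mismatch_never_matches(self):
        f = self._feature([0.0, 0.0, 0.0], ptype=FeatureType.HBD)
        p = PharmacophorePoint(FeatureType.HBA, np.zeros(3), 5.0, key=True)
        assert not point_matched([f], p)[0]

    def test_nearest_feature_wins(self):
        near = self._feature([0.5, 0, 0], atoms=(3,))
        far = self._feature([0.9, 0, 0], atoms=(1,))
        p = PharmacophorePoint(FeatureType.HYD, np.zeros(3), 1.0, key=True)
        ok, best, _ = point_matched([far, near], p)
        assert ok and best is near

    def test_brute_force_oracle_agreement(self, small_library, toy_hypothesis):
        """Matching agrees with an exhaustive scan over (feature, point) pairs."""
        poses, _ = small_library
        for pose in poses[:10]:
            feats = perceive_features(pose)
            for point in toy_hypothesis.points:
                ok, best, d = point_matched(feats, point)
                same = [
                    (float(np.linalg.norm(f.centroid - point.center)), sorted(f.atom_indices), f)
                    for f in feats if f.ptype is point.ptype
                ]
                expect = bool(same) and min(x[0] for x in same) <= point.radius
                assert ok == expect
                if ok:
                    assert d == pytest.approx(min(x[0] for x in same))


class TestMatchHypothesis:
    def test_fixture_poses_match_all_key_points(self, small_library, toy_hypothesis):
        poses, _ = small_library
        for pose in poses:
            report = match_hypothesis(pose, toy_hypothesis)
            assert report.all_key_matched
            assert report.key_atoms

    def test_translated_pose_fails(self, small_library, toy_hypothesis):
        poses, _ = small_library
        pose = poses[0]
        shift = 2 * max(p.radius for p in toy_hypothesis.points) + 5.0
        moved = Chem.Mol(pose.mol)
        conf = moved.GetConformer()
        for i in range(moved.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, type(p)(p.x + shift, p.y, p.z))
        report = match_hypothesis(Pose("moved", moved), toy_hypothesis)
        assert not report.all_key_matched

    def test_rigid_motion_invariance(self, small_library, toy_hypothesis):
        """Rotating+translating pose and hypothesis together leaves the report
        unchanged."""
        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = 1.1
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = np.array([4.0, -2.0, 7.5])

        poses, _ = small_library
        for pose in poses[:5]:
            ref = match_hypothesis(pose, toy_hypothesis)
            moved = Chem.Mol(pose.mol)
            conf = moved.GetConformer()
            new = (R @ pose.coords.T).T + t
            for i in range(moved.GetNumAtoms()):
                p = conf.GetAtomPosition(i)
                conf.SetAtomPosition(i, type(p)(*map(float, new[i])))
            out = match_hypothesis(
                Pose(pose.structure_id, moved), toy_hypothesis.transformed(R, t)
            )
            assert out.all_key_matched == ref.all_key_matched
            assert out.key_atoms == ref.key_atoms
            for a, b in zip(ref.matches, out.matches):
                assert a.matched == b.matched
                assert a.distance == pytest.approx(b.distance, abs=1e-8)

    def test_radius_monotonicity(self, small_library):
        """Enlarging any radius never unmatches a matched point."""
        poses, _ = small_library
        from scaffenum import make_toy_hypothesis

        tight = make_toy_hypothesis(radius=1.0)
        loose = make_toy_hypothesis(radius=2.5)
        for pose in poses[:10]:
            before = match_hypothesis(pose, tight)
            after = match_hypothesis(pose, loose)
            for a, b in zip(before.matches, after.matches):
                if a.matched:
                    assert b.matched

    def test_zero_key_points_rejected_at_construction(self):
        with pytest.raises(ValueError):
            PharmacophoreHypothesis(
                "bad",
                [PharmacophorePoint(FeatureType.HYD, np.zeros(3), 1.0, key=False)],
            )
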