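import pytest
from rdkit import Chem

from scaffenum import (
    Pose,
    brics_fragments_with_intermediates,
    collect_crude_scaffolds,
    extract_peripheral_fragments,
    extract_primary_scaffold,
    join,
    match_hypothesis,
    neutralize,
    scaffold_from_smiles,
)
from scaffenum.io_formats import DataError, FragmentRecord

from oracles import oracle_fragment_sets, oracle_minimal_qualifying


class TestBricsIntermediates:
    def test_single_cleavable_bond(self):
        # ethylbenzene: one BRICS bond -> parent + two one-port pieces
        cands = brics_fragments_with_intermediates(Chem.MolFromSmiles("CCc1ccccc1"))
        assert len(cands) == 3
        ports = sorted(c.n_ports for c in cands)
        assert ports == [0, 1, 1]

    def test_two_bond_linear_backbone_matches_subset_oracle(self):
        # two cleavable bonds in a row: cut-sets {}, {1}, {2}, {1,2} give
        # 1 + 2 + 2 + 3 pieces before dedup
        mol = Chem.MolFromSmiles("CCOc1ccccc1")
        from oracles import brics_bond_pairs
        assert len(brics_bond_pairs(mol)) == 2
        expected, before_dedup = oracle_fragment_sets(mol, max_cuts=6)
        assert before_dedup == 1 + 2 + 2 + 3
        cands = brics_fragments_with_intermediates(mol)
        assert {c.atom_set for c in cands} == set(expected)
        for c in cands:
            ports, has_ring = expected[c.atom_set]
            assert (c.n_ports, c.has_ring) == (ports, has_ring)

    def test_benzene_yields_only_zero_port_parent(self):
        cands = brics_fragments_with_intermediates(Chem.MolFromSmiles("c1ccccc1"))
        assert len(cands) == 1 and cands[0].n_ports == 0

    def test_oracle_equivalence_on_fixture_molecules(self, small_library):
        poses, _ = small_library
        for pose in poses[:8]:
            expected, _ = oracle_fragment_sets(pose.mol, max_cuts=6)
            got = {c.atom_set: (c.n_ports, c.has_ring)
                   for c in brics_fragments_with_intermediates(pose)}
            assert got == expected


class TestNeutralize:
    @pytest.mark.parametrize(
        "smiles,expected,n_flagged",
        [
            ("[NH3+]CC(=O)[O-]", "NCC(=O)O", 0),
            ("c1ccccc1", "c1ccccc1", 0),
            ("C[N+](C)(C)C", "C[N+](C)(C)C", 1),
        ],
    )
    def test_charge_removal_rules(self, smiles, expected, n_flagged):
        out, flagged = neutralize(smiles)
        assert out == Chem.CanonSmiles(expected)
        assert len(flagged) == n_flagged

    def test_unparseable_raises(self):
        with pytest.raises(DataError):
            neutralize("][")


class TestCollectCrude:
    def test_duplicates_merge_provenance(self):
        a = scaffold_from_smiles("[1*]c1ccc(N)cc1")
        b = scaffold_from_smiles("[1*]c1ccc(cc1)N")  # same structure, other SMILES
        crude = collect_crude_scaffolds([(a, "m1", "e1"), (b, "m2", "e2")])
        assert len(crude) == 1
        (prov,) = crude.provenance.values()
        assert prov == [("m1", "e1"), ("m2", "e2")]

    def test_charged_scaffold_neutralized_before_dedup(self):
        charged = scaffold_from_smiles("[1*]c1ccc(C(=O)[O-])cc1")
        neutral = scaffold_from_smiles("[1*]c1ccc(C(=O)O)cc1")
        crude = collect_crude_scaffolds([(charged, "m1", "e1"), (neutral, "m2", "e1")])
        assert len(crude) == 1

    def test_empty_input(self):
        assert len(collect_crude_scaffolds([])) == 0

    def test_idempotence(self, recovery_library, toy_hypothesis):
        poses, _ = recovery_library
        records = []
        for pose in poses[:30]:
            s = extract_primary_scaffold(pose, toy_hypothesis)
            if s is not None:
                records.append((s, pose.structure_id, "e1"))
        once = collect_crude_scaffolds(records)
        twice = collect_crude_scaffolds(once.records())
        assert set(once.scaffolds) == set(twice.scaffolds)


class TestExtractPrimaryScaffold:
    def test_planted_scaffold_recovered(self, small_library, toy_hypothesis):
        poses, truth = small_library
        for pose, t in zip(poses[:15], truth[:15]):
            s = extract_primary_scaffold(pose, toy_hypothesis)
            assert s is not None and s.smiles == t["scaffold"]

    def test_extracted_scaffold_is_oracle_minimal(self, small_library, toy_hypothesis):
        poses, _ = small_library
        for pose in poses[:10]:
            report = match_hypothesis(pose, toy_hypothesis)
            s = extract_primary_scaffold(pose, toy_hypothesis, report=report)
            minimal = oracle_minimal_qualifying(pose.mol, report.key_atoms, max_cuts=6)
            assert s is not None
            assert frozenset(s.atom_map) in minimal

    def test_acyclic_molecule_yields_none(self, toy_hypothesis):
        from scaffenum import make_toy_library
        # an acyclic pose cannot satisfy the ring rule regardless of matching
        from rdkit.Chem import AllChem
        mol = Chem.MolFromSmiles("CCOCCNCC(=O)O")
        AllChem.EmbedMolecule(mol, randomSeed=3)
        pose = Pose("acyclic", mol)
        assert extract_primary_scaffold(pose, toy_hypothesis) is None

    def test_unmatched_pose_yields_none(self, small_library, toy_hypothesis):
        poses, _ = small_library
        pose = poses[0]
        moved = Chem.Mol(pose.mol)
        conf = moved.GetConformer()
        for i in range(moved.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, type(p)(p.x + 50.0, p.y, p.z))
        assert extract_primary_scaffold(Pose("far", moved), toy_hypothesis) is None

    def test_scaffold_invariants_hold(self, small_library, toy_hypothesis):
        poses, _ = small_library
        for pose in poses[:15]:
            s = extract_primary_scaffold(pose, toy_hypothesis)
            assert s is not None
            assert 1 <= s.n_ports <= 3
            assert s.mol().GetRingInfo().NumRings() >= 1
            # canonical form stable under re-parse
            assert scaffold_from_smiles(s.smiles).smiles == s.smiles


class TestPeripheralFragments:
    def test_planted_sides_recovered(self, small_library, toy_hypothesis):
        poses, truth = small_library
        for pose, t in zip(poses[:15], truth[:15]):
            s = extract_primary_scaffold(pose, toy_hypothesis)
            frs = extract_peripheral_fragments(pose, s, toy_hypothesis)
            sides = {f.side: f.smiles for f in frs}
            assert sides == {"left": t["left"], "right": t["right"]}

    def test_rejoin_reconstitutes_parent(self, small_library, toy_hypothesis):
        poses, _ = small_library
        for pose in poses[:10]:
            s = extract_primary_scaffold(pose, toy_hypothesis)
            frs = extract_peripheral_fragments(pose, s, toy_hypothesis)
            left = next(f for f in frs if f.side == "left")
            right = next(f for f in frs if f.side == "right")
            rebuilt = join(s, left, right)
            assert rebuilt == Chem.MolToSmiles(pose.mol)

    def test_pose_identical_to_scaffold_yields_nothing(self, toy_hypothesis):
        from scaffenum.fixtures import _layout_pose
        from rdkit.Geometry import Point3D
        mol = Chem.MolFromSmiles("Nc1ccc(O)cc1")
        coords = _layout_pose(mol, set(range(mol.GetNumAtoms())), set(), set(), toy_hypothesis)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, Point3D(*map(float, coords[i])))
        conf.Set3D(True)
        mol.AddConformer(conf)
        pose = Pose("bare", mol)
        scaffold = scaffold_from_smiles("[1*]c1ccc(N)cc1O")  # placeholder ports
        scaffold = type(scaffold)(
            smiles=scaffold.smiles, ports=scaffold.ports,
            atom_map=tuple(range(mol.GetNumAtoms())),
        )
        assert extract_peripheral_fragments(pose, scaffold, toy_hypothesis) == []

    def test_source_id_carries_pose_identity(self, small_library, toy_hypothesis):
        poses, _ = small_library
        pose = poses[0]
        s = extract_primary_scaffold(pose, toy_hypothesis)
        for rec in extract_peripheral_fragments(pose, s, toy_hypothesis):
            assert rec.source_id == pose.structure_id
            assert sum(a.GetAtomicNum() == 0
                       for a in Chem.MolFromSmiles(rec.smiles).GetAtoms()) == 1
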