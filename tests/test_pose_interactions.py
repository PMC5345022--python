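"""Docking-pose consumption and geometric interaction rules."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foodvs.fixtures import make_toy_pocket
from foodvs.pose_interactions import (PoseAtom, PoseFilterRules, PosePacket,
                                      Receptor, detect_hbonds,
                                      detect_salt_bridge, filter_poses,
                                      read_poses)

PDBQT_3_MODELS = """MODEL 1
REMARK VINA RESULT:      -7.2      0.000      0.000
ATOM      1  N   LIG A   1      -1.000  -2.000  -1.500  1.00  0.00    -0.030 N
ATOM      2  C   LIG A   1       0.000  -3.000  -1.000  1.00  0.00     0.100 C
ENDMDL
MODEL 2
REMARK VINA RESULT:      -6.5      1.200      2.100
ATOM      1  N   LIG A   1       4.000   2.000   3.000  1.00  0.00    -0.030 N
ATOM      2  C   LIG A   1       5.000   2.000   3.000  1.00  0.00     0.100 C
ENDMDL
MODEL 3
REMARK VINA RESULT:      -6.1      2.000      3.000
ATOM      1  N   LIG A   1       6.000   2.000   3.000  1.00  0.00    -0.030 N
ATOM      2  C   LIG A   1       7.000   2.000   3.000  1.00  0.00     0.100 C
ENDMDL
"""


def cationic_pose(n_pos=(-1.0, -2.0, -1.5), score=-7.0, with_phenol=False):
    atoms = [PoseAtom("N", "N1", np.array(n_pos), formal_charge=1),
             PoseAtom("C", "C1", np.array(n_pos) + np.array([1.4, 0, 0]))]
    if with_phenol:
        atoms += [PoseAtom("O", "O1", np.array([2.9, -3.2, 0.5])),
                  PoseAtom("H", "H1", np.array([2.9, -4.1, 0.5]))]
    return PosePacket(atoms, score=score)


def neutral_pose():
    return PosePacket([PoseAtom("C", "C1", np.array([0.0, -2.0, 0.0])),
                       PoseAtom("O", "O1", np.array([1.0, -2.0, 0.0]))],
                      score=-5.0)


class TestReadPoses:
    def test_multi_model_pdbqt(self, tmp_path):
        f = tmp_path / "out.pdbqt"
        f.write_text(PDBQT_3_MODELS)
        packets = read_poses(f)
        assert len(packets) == 3
        assert [p.score for p in packets] == [-7.2, -6.5, -6.1]
        assert [p.index for p in packets] == [0, 1, 2]  # file order kept
        assert packets[0].atoms[0].partial_charge == pytest.approx(-0.03)

    def test_sdf_without_scores(self, tmp_path):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        AllChem.EmbedMolecule(mol, randomSeed=5)
        f = tmp_path / "poses.sdf"
        w = Chem.SDWriter(str(f))
        w.write(mol)
        w.write(mol)
        w.close()
        packets = read_poses(f)
        assert len(packets) == 2
        assert all(p.score is None for p in packets)

    def test_malformed_atom_line_fatal_with_context(self, tmp_path):
        f = tmp_path / "bad.pdbqt"
        f.write_text("MODEL 1\nATOM      1  N   LIG A   1      xxx\nENDMDL\n")
        with pytest.raises(ValueError, match="bad.pdbqt:2"):
            read_poses(f)


class TestSaltBridge:
    def test_cation_near_carboxylate(self, pocket_pdb):
        ok, dist = detect_salt_bridge(cationic_pose(), pocket_pdb, "ASP 114")
        assert ok and dist == pytest.approx(2.6926, abs=1e-3)

    def test_translated_pose_fails_distance_rule(self, pocket_pdb):
        far = cationic_pose().transformed(np.eye(3), np.array([10.0, 10.0, 10.0]))
        ok, dist = detect_salt_bridge(far, pocket_pdb, "ASP 114")
        assert not ok and dist > 4.0

    def test_no_cation_reports_infinity(self, pocket_pdb):
        ok, dist = detect_salt_bridge(neutral_pose(), pocket_pdb, "ASP 114")
        assert not ok and math.isinf(dist)

    def test_ballesteros_weinstein_alias(self, pocket_pdb):
        ok, _ = detect_salt_bridge(cationic_pose(), pocket_pdb, "3.32")
        assert ok

    def test_missing_residue_is_error(self, pocket_pdb):
        with pytest.raises(KeyError):
            detect_salt_bridge(cationic_pose(), pocket_pdb, "ASP 999")

    def test_invariant_under_joint_rigid_motion(self, pocket_pdb, tmp_path, rng):
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        trans = np.array([3.0, -2.0, 7.0])
        _, d0 = detect_salt_bridge(cationic_pose(), pocket_pdb, "ASP 114")
        # transform pocket text and pose together
        rec = Receptor.from_pdb(pocket_pdb)
        for atom in rec.structure.get_atoms():
            atom.set_coord(rot @ atom.get_coord() + trans)
        moved_pose = cationic_pose().transformed(rot, trans)
        ok, d1 = detect_salt_bridge(moved_pose, rec, "ASP 114")
        assert ok and d1 == pytest.approx(d0, abs=1e-5)


class TestHbonds:
    def test_single_serine_contact_not_two(self, pocket_pdb):
        # phenolic OH reaches Ser197 OG but not Ser193 OG
        bonds = detect_hbonds(cationic_pose(with_phenol=True), pocket_pdb,
                              ["SER 193", "SER 197"])
        acceptors = {b.acceptor for b in bonds}
        assert acceptors == {"SER197:OG"}

    def test_near_linear_hydrogen_accepted(self, pocket_pdb):
        bonds = detect_hbonds(cationic_pose(with_phenol=True), pocket_pdb,
                              ["SER 197"])
        assert len(bonds) == 1
        assert bonds[0].angle > 150

    def test_bent_hydrogen_rejected(self, pocket_pdb):
        pose = cationic_pose(with_phenol=True)
        pose.atoms[3] = PoseAtom("H", "H1", np.array([2.9, -2.3, 0.5]))  # bent
        assert detect_hbonds(pose, pocket_pdb, ["SER 197"]) == []

    def test_everything_far_apart_is_empty(self, pocket_pdb):
        far = cationic_pose(with_phenol=True).transformed(
            np.eye(3), np.array([20.0, 20.0, 20.0]))
        assert detect_hbonds(far, pocket_pdb, ["SER 193", "SER 197"]) == []


class TestFilterPoses:
    def test_salt_bridge_is_mandatory(self, pocket_pdb):
        poses = [cationic_pose(score=-7.0),
                 cationic_pose(n_pos=(8.0, 8.0, 8.0), score=-8.0),
                 neutral_pose(),
                 cationic_pose(score=-6.0),
                 cationic_pose(n_pos=(9.0, 9.0, 9.0), score=-9.0)]
        accepted, reports = filter_poses(poses, pocket_pdb)
        assert len(accepted) == 2
        assert [r.accepted for r in reports] == [True, False, False, True, False]
        assert all(r.accepted <= r.salt_bridge for r in reports)

    def test_empty_input(self, pocket_pdb):
        accepted, reports = filter_poses([], pocket_pdb)
        assert accepted == [] and reports == []

    def test_score_ranking_stable_on_ties(self, pocket_pdb):
        a = cationic_pose(score=-7.0)
        b = cationic_pose(score=-7.0)
        a.index, b.index = 0, 1
        accepted, _ = filter_poses([a, b], pocket_pdb)
        assert [p.index for p in accepted] == [0, 1]

    def test_tightening_dmax_never_accepts_more(self, pocket_pdb):
        poses = [cationic_pose(), cationic_pose(n_pos=(-2.5, -3.0, -2.0)),
                 cationic_pose(n_pos=(8.0, 8.0, 8.0))]
        counts = []
        for dmax in (6.0, 4.0, 3.0, 2.0):
            rules = PoseFilterRules(salt_bridge_dmax=dmax)
            accepted, _ = filter_poses(poses, pocket_pdb, rules)
            counts.append(len(accepted))
        assert counts == sorted(counts, reverse=True)

    def test_optional_hbond_rule(self, pocket_pdb):
        rules = PoseFilterRules(hbond_residues=["SER 197"], require_hbond=True)
        accepted, _ = filter_poses([cationic_pose(with_phenol=True),
                                    cationic_pose()], pocket_pdb, rules)
        assert len(accepted) == 1
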