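"""Pose construction, transfer, clash relief and consensus."""

import numpy as np
import pytest

from conftest import random_rotation
from pocketrepo import fixtures, pocketalign
from pocketrepo.geometry import RigidTransform
from pocketrepo.reposition import (
    DrugPose,
    TemplateComplex,
    clash_penalty,
    consensus_pose,
    detect_clashes,
    relieve_clashes,
    template_dock,
    transfer_by_alignment,
)
from pocketrepo.structio import SmallMolecule


def _mol(points, id="m"):
    return SmallMolecule(
        id=id, atoms=[("C", 0, np.asarray(p, float), False) for p in points], bonds=[]
    )


class TestTemplateDock:
    def test_identity_everything_reproduces_template_ligand(self, toy_complex):
        structure, ligand, _ = toy_complex
        tc = TemplateComplex(
            structure=structure,
            ligand=ligand,
            global_transform=RigidTransform.identity(),
            chemical_mapping=[(i, i) for i in range(ligand.n_heavy_atoms)],
        )
        pose = template_dock(structure, tc, ligand)
        assert np.allclose(pose.heavy_coords(), ligand.heavy_coords(), atol=1e-9)

    def test_known_global_transform_applied_exactly(self, toy_complex, rng):
        structure, ligand, _ = toy_complex
        rot = random_rotation(rng)
        transform = RigidTransform(rotation=rot, translation=np.array([4.0, -2.0, 1.0]))
        tc = TemplateComplex(
            structure=structure,
            ligand=ligand,
            global_transform=transform,
            chemical_mapping=[(i, i) for i in range(ligand.n_heavy_atoms)],
        )
        pose = template_dock(structure, tc, ligand)
        assert np.allclose(
            pose.heavy_coords(), transform.apply(ligand.heavy_coords()), atol=1e-9
        )

    def test_unmapped_atom_carried_rigidly(self, toy_complex):
        structure, ligand, _ = toy_complex
        extra = ligand.heavy_coords()[0] + np.array([0.0, 0.0, 2.0])
        drug = SmallMolecule(
            id="drug",
            atoms=list(ligand.atoms) + [("N", 0, extra, False)],
            bonds=[],
        )
        tc = TemplateComplex(
            structure=structure,
            ligand=ligand,
            global_transform=RigidTransform.identity(),
            chemical_mapping=[(i, i) for i in range(ligand.n_heavy_atoms)],
        )
        pose = template_dock(structure, tc, drug)
        xyz = pose.heavy_coords()
        assert np.allclose(xyz[:-1], ligand.heavy_coords(), atol=1e-9)
        assert np.allclose(xyz[-1], extra, atol=1e-9)  # identity fit keeps it in place

    def test_short_mapping_rejected(self, toy_complex):
        structure, ligand, _ = toy_complex
        tc = TemplateComplex(
            structure=structure,
            ligand=ligand,
            global_transform=RigidTransform.identity(),
            chemical_mapping=[(0, 0), (1, 1)],
        )
        with pytest.raises(ValueError, match="3 atoms"):
            template_dock(structure, tc, ligand)


class TestTransfer:
    def test_identity_alignment_keeps_coordinates(self, toy_pocket, toy_pose):
        pocket, _ = toy_pocket
        result = pocketalign.match_pockets(pocket, pocket)
        moved = transfer_by_alignment(toy_pose, result.alignment, "dest")
        assert np.allclose(moved.heavy_coords(), toy_pose.heavy_coords(), atol=1e-9)

    def test_pure_translation_applied_to_every_atom(self, toy_pose):
        alignment = pocketalign.PocketAlignment(
            pairs=[(i, i, 1.0) for i in range(5)],
            transform=RigidTransform(rotation=np.eye(3),
                                     translation=np.array([10.0, 0.0, 0.0])),
            aligned_rmsd=0.0,
        )
        moved = transfer_by_alignment(toy_pose, alignment, "dest")
        assert np.allclose(
            moved.heavy_coords() - toy_pose.heavy_coords(), [10.0, 0.0, 0.0]
        )

    def test_intra_ligand_distances_preserved(self, toy_pose, rng):
        alignment = pocketalign.PocketAlignment(
            pairs=[(i, i, 1.0) for i in range(5)],
            transform=RigidTransform(rotation=random_rotation(rng),
                                     translation=rng.normal(size=3) * 5),
            aligned_rmsd=1.0,
        )
        moved = transfer_by_alignment(toy_pose, alignment, "dest")
        a = toy_pose.heavy_coords()
        b = moved.heavy_coords()
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        assert np.allclose(da, db, atol=1e-9)

    def test_failed_alignment_rejected(self, toy_pose):
        alignment = pocketalign.PocketAlignment(
            pairs=[(i, i, 0.5) for i in range(5)],
            transform=RigidTransform.identity(),
            aligned_rmsd=30.0,
            failed=True,
        )
        with pytest.raises(ValueError, match="failed"):
            transfer_by_alignment(toy_pose, alignment, "dest")


class TestClashes:
    def test_distant_ligand_has_no_clashes(self, toy_complex):
        structure, _, _ = toy_complex
        pose = DrugPose(
            drug=_mol([[100, 0, 0], [101, 0, 0], [102, 0, 0], [103, 0, 0]]),
            source_target_id="s", via="t",
        )
        assert detect_clashes(pose, structure) == []

    def test_single_close_pair_reported(self, toy_complex):
        structure, _, _ = toy_complex
        p_xyz, _ = structure.protein_heavy_atoms()
        outer = p_xyz[np.argmax(np.linalg.norm(p_xyz, axis=1))]
        direction = outer / np.linalg.norm(outer)
        # radially outward: only the outermost atom is within the cutoff
        probe = outer + direction * 2.0
        pose = DrugPose(
            drug=_mol([probe, probe + direction * 50, probe + direction * 51,
                       probe + direction * 52]),
            source_target_id="s", via="t",
        )
        clashes = detect_clashes(pose, structure)
        assert len(clashes) == 1
        assert clashes[0][2] == pytest.approx(2.0)

    def test_boundary_is_not_a_clash(self, toy_complex):
        structure, _, _ = toy_complex
        # isolate one protein atom direction and sit exactly at the cutoff
        probe = _mol([[100, 0, 0], [101, 0, 0], [102, 0, 0], [103, 0, 0]])
        pose = DrugPose(drug=probe, source_target_id="s", via="t")
        p_xyz, _ = structure.protein_heavy_atoms()
        # place one ligand atom exactly 2.5 Å from the farthest protein atom
        far = p_xyz[np.argmax(p_xyz[:, 0])]
        xyz = probe.heavy_coords()
        xyz[0] = far + np.array([2.5, 0.0, 0.0])
        pose = DrugPose(drug=probe.with_coords(xyz), source_target_id="s", via="t")
        assert all(d < 2.5 for _, _, d in detect_clashes(pose, structure))
        assert not any(
            abs(d - 2.5) < 1e-9 for _, _, d in detect_clashes(pose, structure)
        )


class TestRelieveClashes:
    def test_clash_free_input_returned_unchanged(self, toy_complex):
        structure, _, _ = toy_complex
        pose = DrugPose(
            drug=_mol([[100, 0, 0], [101, 0, 0], [102, 0, 0], [103, 0, 0]]),
            source_target_id="s", via="t",
        )
        refined, residual = relieve_clashes(pose, structure)
        assert residual == []
        assert np.array_equal(refined.heavy_coords(), pose.heavy_coords())

    def test_small_clash_resolved_with_small_shift(self, toy_complex):
        structure, _, _ = toy_complex
        p_xyz, _ = structure.protein_heavy_atoms()
        # ligand just outside the structure, one atom 2.0 Å from the outermost atom
        outer = p_xyz[np.argmax(np.linalg.norm(p_xyz, axis=1))]
        direction = outer / np.linalg.norm(outer)
        base = outer + direction * 2.0
        pts = [base + direction * k for k in range(4)]
        pose = DrugPose(drug=_mol(pts), source_target_id="s", via="t")
        assert detect_clashes(pose, structure)
        refined, residual = relieve_clashes(pose, structure)
        assert residual == []
        displacement = np.linalg.norm(
            refined.heavy_coords()[0] - pose.heavy_coords()[0]
        )
        assert displacement <= 1.0

    def test_penalty_never_increases_and_geometry_unchanged(self, toy_complex):
        structure, _, _ = toy_complex
        p_xyz, _ = structure.protein_heavy_atoms()
        pose = DrugPose(
            drug=_mol([p_xyz[0] + [0.5, 0, 0], p_xyz[0] + [1.0, 0.5, 0],
                       p_xyz[0] + [0, 1.5, 0.5], p_xyz[0] + [1.5, 1.5, 1.5]]),
            source_target_id="s", via="t",
        )
        before = clash_penalty(pose.heavy_coords(), p_xyz)
        refined, _ = relieve_clashes(pose, structure)
        after = clash_penalty(refined.heavy_coords(), p_xyz)
        assert after <= before + 1e-12
        a, b = pose.heavy_coords(), refined.heavy_coords()
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        assert np.allclose(da, db, atol=1e-9)

    def test_enclosed_ligand_reports_residual_and_caps_displacement(self, rng):
        # dense synthetic cage: ligand cannot escape within 3 Å
        from pocketrepo.structio import AtomRecord, MolecularStructure, Residue

        cage_atoms = []
        k = 0
        for x in np.arange(-6, 6.1, 1.5):
            for y in np.arange(-6, 6.1, 1.5):
                for z in np.arange(-6, 6.1, 1.5):
                    if np.linalg.norm([x, y, z]) > 2.0:
                        k += 1
                        cage_atoms.append(
                            AtomRecord(serial=k, name="CA", element="C",
                                       coords=np.array([x, y, z]))
                        )
        res = Residue(chain_id="A", seq_number=1, res_name="GLY",
                      atoms=cage_atoms[:1])
        # spread atoms over residues to satisfy unique atom names
        residues = [
            Residue(chain_id="A", seq_number=i + 1, res_name="GLY", atoms=[a])
            for i, a in enumerate(cage_atoms)
        ]
        cage = MolecularStructure(id="cage", chains={"A": residues}, ligands=[])
        pose = DrugPose(
            drug=_mol([[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5]]),
            source_target_id="s", via="t",
        )
        refined, residual = relieve_clashes(pose, cage)
        assert residual  # honestly reported
        displacement = np.linalg.norm(
            refined.heavy_coords()[0] - pose.heavy_coords()[0]
        )
        assert displacement <= 3.0 + 1e-9


class TestConsensus:
    def _pose(self, offset, id="drug"):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        pts = pts + np.asarray(offset, float)
        return DrugPose(drug=_mol(pts, id=id), source_target_id="s", via="t")

    def test_majority_pose_wins(self):
        shift = np.array([5.0, 0.0, 0.0])
        poses = [self._pose([0, 0, 0]), self._pose([0, 0, 0]), self._pose(shift)]
        result = consensus_pose(poses)
        assert result.typical_index == 0  # lowest index among the identical pair
        assert result.spread[0] == pytest.approx(2.5)  # mean of {0, 5}
        assert result.rmsd_matrix[0, 2] == pytest.approx(5.0)

    def test_all_identical(self):
        poses = [self._pose(0.0)] * 3
        result = consensus_pose(poses)
        assert result.typical_index == 0
        assert np.allclose(result.spread, 0.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            consensus_pose([self._pose(0.0)])

    def test_triangle_inequality_on_random_poses(self, rng):
        poses = [self._pose(rng.normal(size=3) * 4) for _ in range(5)]
        m = consensus_pose(poses).rmsd_matrix
        n = len(poses)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_mapping_restricts_comparison(self):
        a = self._pose(0.0)
        b_pts = a.heavy_coords().copy()
        b_pts[3] += 10.0  # differ only in the last atom
        b = DrugPose(drug=_mol(b_pts), source_target_id="s", via="t")
        full = consensus_pose([a, b]).rmsd_matrix[0, 1]
        mapped = consensus_pose([a, b], mapping=[0, 1, 2]).rmsd_matrix[0, 1]
        assert mapped == pytest.approx(0.0, abs=1e-12)
        assert full > 0
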