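"""Drug pose construction and transfer between matched pockets.

Poses enter a source pocket by two-step template-based docking (a globally
superposed holo template donates its bound ligand's position; the drug is
least-squares fitted onto the template ligand through a chemical atom
mapping) and move to a destination pocket by applying the rigid transform of
a significant pocket alignment. Transfers are rigid: intra-ligand geometry
is preserved exactly.

Steric clashes between a transferred drug and the destination protein are
relieved by a deterministic rigid-body translation search that greedily
descends the clash-overlap penalty Σ (cutoff - d)² over clashing pairs; the
total displacement is capped, and any residual clashes are reported rather
than hidden. When the same drug reaches one destination through several
alignments, the most typical pose is the one with minimal mean heavy-atom
RMSD to the others, computed without re-superposition since all poses share
the destination frame (re-superposing would erase the binding-mode
difference being measured).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import RigidTransform, kabsch_superpose
from .pocketalign import PocketAlignment
from .structio import MolecularStructure, SmallMolecule

__all__ = [
    "TemplateComplex",
    "DrugPose",
    "ConsensusResult",
    "template_dock",
    "transfer_by_alignment",
    "detect_clashes",
    "clash_penalty",
    "relieve_clashes",
    "consensus_pose",
]

CLASH_CUTOFF = 2.5  # Å, heavy-atom; strict inequality at the boundary
MAX_RELIEF_TRANSLATION = 3.0  # Å
RELIEF_STEP = 0.1  # Å


@dataclass
class TemplateComplex:
    """A holo template aligned onto the target, donating its ligand position."""

    structure: MolecularStructure
    ligand: SmallMolecule
    global_transform: RigidTransform  # template frame -> target frame
    chemical_mapping: list[tuple[int, int]]  # template-ligand heavy atom -> drug heavy atom

    def __post_init__(self) -> None:
        t_idx = [m[0] for m in self.chemical_mapping]
        d_idx = [m[1] for m in self.chemical_mapping]
        if len(set(t_idx)) != len(t_idx) or len(set(d_idx)) != len(d_idx):
            raise ValueError("chemical mapping must be injective on heavy atoms")


@dataclass
class DrugPose:
    """A drug with 3D coordinates in some target's frame, with provenance."""

    drug: SmallMolecule
    source_target_id: str
    via: str  # alignment id or template id

    def __post_init__(self) -> None:
        if not self.drug.has_coords:
            raise ValueError(f"pose of {self.drug.id!r} lacks coordinates")

    def heavy_coords(self) -> np.ndarray:
        return self.drug.heavy_coords()


@dataclass
class ConsensusResult:
    """Pairwise pose agreement and the most typical pose."""

    typical_index: int
    rmsd_matrix: np.ndarray
    spread: np.ndarray  # per-pose mean RMSD to the others

    def __post_init__(self) -> None:
        m = np.asarray(self.rmsd_matrix, dtype=float)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
            raise ValueError("RMSD matrix must be square and symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("RMSD matrix diagonal must be zero")


def template_dock(
    target: MolecularStructure,
    template: TemplateComplex,
    drug: SmallMolecule,
) -> DrugPose:
    """Two-step similarity-based docking of a drug into a target pocket.

    The template ligand is moved into the target frame by the global
    template->target transform; the drug's mapped heavy atoms are then
    least-squares fitted onto the mapped template-ligand atoms, and unmapped
    drug atoms are carried rigidly by the same transform.
    """
    if len(template.chemical_mapping) < 3:
        raise ValueError("chemical mapping must cover >= 3 atoms (fit underdetermined)")
    if not drug.has_coords:
        raise ValueError(f"drug {drug.id!r} needs 3D coordinates for template docking")
    template_lig_xyz = template.global_transform.apply(template.ligand.heavy_coords())
    drug_xyz = drug.heavy_coords()
    t_idx = np.array([m[0] for m in template.chemical_mapping], dtype=int)
    d_idx = np.array([m[1] for m in template.chemical_mapping], dtype=int)
    sup = kabsch_superpose(drug_xyz[d_idx], template_lig_xyz[t_idx])
    placed = sup.transform.apply(drug_xyz)
    return DrugPose(
        drug=drug.with_coords(placed),
        source_target_id=target.id,
        via=f"template:{template.structure.id}",
    )


def transfer_by_alignment(
    pose: DrugPose,
    alignment: PocketAlignment,
    destination_id: str,
    alignment_id: Optional[str] = None,
) -> DrugPose:
    """Move a pose from the source frame into the destination frame.

    Applies the alignment's rigid transform to every atom; all intra-ligand
    distances are preserved exactly.
    """
    if alignment.failed:
        raise ValueError("cannot transfer through a failed alignment")
    moved = alignment.transform.apply(pose.heavy_coords())
    return DrugPose(
        drug=pose.drug.with_coords(moved),
        source_target_id=pose.source_target_id,
        via=alignment_id or f"alignment:{pose.source_target_id}->{destination_id}",
    )


def detect_clashes(
    pose: DrugPose | SmallMolecule,
    structure: MolecularStructure,
    clash_cutoff: float = CLASH_CUTOFF,
) -> list[tuple[int, int, float]]:
    """Protein-heavy/ligand-heavy pairs strictly closer than the cutoff.

    Returns (protein atom index, ligand heavy-atom index, distance) triples;
    a pair at exactly the cutoff is not a clash.
    """
    lig = pose.drug if isinstance(pose, DrugPose) else pose
    p_xyz, _ = structure.protein_heavy_atoms()
    l_xyz = lig.heavy_coords()
    d = np.sqrt(np.sum((p_xyz[:, None, :] - l_xyz[None, :, :]) ** 2, axis=-1))
    out = []
    for pi, li in zip(*np.nonzero(d < clash_cutoff)):
        out.append((int(pi), int(li), float(d[pi, li])))
    return out


def clash_penalty(
    lig_xyz: np.ndarray, p_xyz: np.ndarray, clash_cutoff: float = CLASH_CUTOFF
) -> float:
    """Quadratic overlap penalty Σ (cutoff - d)² over clashing pairs."""
    d = np.sqrt(np.sum((p_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=-1))
    overlap = clash_cutoff - d
    return float(np.sum(np.square(overlap[overlap > 0])))


_DIRECTIONS = None


def _unit_directions() -> np.ndarray:
    """26 lattice directions for the greedy translation search."""
    global _DIRECTIONS
    if _DIRECTIONS is None:
        dirs = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    v = np.array([dx, dy, dz], dtype=float)
                    dirs.append(v / np.linalg.norm(v))
        _DIRECTIONS = np.asarray(dirs)
    return _DIRECTIONS


def relieve_clashes(
    pose: DrugPose,
    structure: MolecularStructure,
    clash_cutoff: float = CLASH_CUTOFF,
    max_translation: float = MAX_RELIEF_TRANSLATION,
    step: float = RELIEF_STEP,
) -> tuple[DrugPose, list[tuple[int, int, float]]]:
    """Rigid-body translation search relieving steric clashes.

    Greedy descent on the clash-overlap penalty: at each step the ligand is
    shifted by ``step`` Å along the direction of steepest penalty decrease
    (26-neighbour lattice), stopping when no clash remains, no direction
    improves, or the total displacement reaches ``max_translation``. The
    penalty never increases and ligand internal geometry is unchanged.
    Returns the refined pose and the residual clash report.
    """
    p_xyz, _ = structure.protein_heavy_atoms()
    xyz = pose.heavy_coords().copy()
    moved = 0.0
    penalty = clash_penalty(xyz, p_xyz, clash_cutoff)
    while penalty > 0 and moved + step <= max_translation + 1e-12:
        best_dir, best_pen = None, penalty
        for direction in _unit_directions():
            cand = clash_penalty(xyz + step * direction, p_xyz, clash_cutoff)
            if cand < best_pen - 1e-15:
                best_dir, best_pen = direction, cand
        if best_dir is None:
            break
        xyz = xyz + step * best_dir
        moved += step
        penalty = best_pen
    refined = DrugPose(
        drug=pose.drug.with_coords(xyz),
        source_target_id=pose.source_target_id,
        via=pose.via,
    )
    residual = detect_clashes(refined, structure, clash_cutoff)
    return refined, residual


def consensus_pose(
    poses: Sequence[DrugPose],
    mapping: Optional[Sequence[int]] = None,
) -> ConsensusResult:
    """Most typical pose among several models of the same drug-target complex.

    Pairwise heavy-atom RMSDs are computed without re-superposition (all
    poses share the destination frame). ``mapping`` optionally restricts the
    comparison to a common heavy-atom subset (indices into the heavy atoms).
    The typical pose minimizes the mean RMSD to the others; ties go to the
    lowest index.
    """
    if len(poses) < 2:
        raise ValueError("consensus needs >= 2 poses")
    coords = [p.heavy_coords() for p in poses]
    if mapping is not None:
        idx = np.asarray(mapping, dtype=int)
        coords = [c[idx] for c in coords]
    n_atoms = {c.shape[0] for c in coords}
    if len(n_atoms) != 1:
        raise ValueError("poses must share the heavy-atom mapping")
    k = len(coords)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = float(
                np.sqrt(np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1)))
            )
    spread = m.sum(axis=1) / (k - 1)
    typical = int(np.argmin(spread))  # argmin keeps the lowest index on ties
    return ConsensusResult(typical_index=typical, rmsd_matrix=m, spread=spread)
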