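"""Binding-pocket construction and pocket-level descriptors.

A pocket is the set of binding residues of a target — either the residues
within a heavy-atom contact cutoff of a bound ligand (holo complexes) or the
residues named by a pocket prediction (annotations) — together with per-
residue physicochemical features, a geometric center, and optionally a
profile of the physicochemical properties predicted for its binders.

The contact definition is 4.5 Å heavy-atom to heavy-atom, the common contact
convention. A predicted pocket center counts as correct when it lies within
8 Å of the geometric center of the bound ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structio import MolecularStructure, PocketAnnotation, Residue, SmallMolecule

__all__ = [
    "ResidueFeatures",
    "Pocket",
    "LigandProfile",
    "features_for_residue",
    "extract_pocket",
    "pocket_from_annotation",
    "annotation_is_correct",
    "ligand_radius_of_gyration",
    "search_box_from_rg",
    "property_profile",
    "confidence_tier",
]

CONTACT_CUTOFF = 4.5  # Å, heavy-atom contact convention
CENTER_CORRECT_THRESHOLD = 8.0  # Å
MIN_POCKET_RESIDUES = 5

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1, "HIS": 1}
_POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS", "ASP", "GLU",
          "LYS", "ARG", "TRP"}
_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}
# Heavy side-chain atom counts of the standard residues
_SIDECHAIN_SIZE = {
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "THR": 3, "VAL": 3, "PRO": 3,
    "ILE": 4, "LEU": 4, "ASN": 4, "ASP": 4, "MET": 4, "GLN": 5, "GLU": 5,
    "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7, "TYR": 8, "TRP": 10,
}


@dataclass(frozen=True)
class ResidueFeatures:
    """Per-residue physicochemical and conservation features."""

    hydrophobicity: float
    charge_class: int  # -1, 0, +1
    polar: bool
    aromatic: bool
    side_chain_size: int
    conservation: float = 1.0

    def __post_init__(self) -> None:
        if self.charge_class not in (-1, 0, 1):
            raise ValueError("charge_class must be -1, 0 or +1")
        if not (0.0 <= self.conservation <= 1.0):
            raise ValueError("conservation must be in [0, 1]")
        if self.side_chain_size < 0:
            raise ValueError("side_chain_size must be non-negative")


def features_for_residue(
    res_name: str, conservation: float = 1.0, side_chain_size: Optional[int] = None
) -> ResidueFeatures:
    """Standard feature vector for a residue type.

    Conservation defaults to 1.0 (uninformative) when no evolutionary
    profile is available, so the feature weighting need not change.
    """
    name = res_name.upper()
    return ResidueFeatures(
        hydrophobicity=KYTE_DOOLITTLE.get(name, 0.0),
        charge_class=_CHARGE.get(name, 0),
        polar=name in _POLAR,
        aromatic=name in _AROMATIC,
        side_chain_size=(
            side_chain_size if side_chain_size is not None
            else _SIDECHAIN_SIZE.get(name, 4)
        ),
        conservation=conservation,
    )


@dataclass(frozen=True)
class LigandProfile:
    """Mean ± population SD of MW / logP / PSA over a set of (putative) binders."""

    mw_mean: float
    mw_sd: float
    logp_mean: float
    logp_sd: float
    psa_mean: float
    psa_sd: float

    def __post_init__(self) -> None:
        if min(self.mw_sd, self.logp_sd, self.psa_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class Pocket:
    """A binding pocket: residues with Cα coordinates and features."""

    target_id: str
    residues: list[tuple[Residue, np.ndarray, ResidueFeatures]]
    center: np.ndarray
    confidence: float = 100.0
    property_profile: Optional[LigandProfile] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise ValueError("pocket center must be finite")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.asarray([c for _, c, _ in self.residues], dtype=float)

    def features(self) -> list[ResidueFeatures]:
        return [f for _, _, f in self.residues]

    def residue_keys(self) -> list[tuple]:
        return [r.key for r, _, _ in self.residues]

    @property
    def alignable(self) -> bool:
        return len(self.residues) >= MIN_POCKET_RESIDUES


def extract_pocket(
    structure: MolecularStructure,
    ligand: SmallMolecule,
    cutoff: float = CONTACT_CUTOFF,
    conservation: float = 1.0,
) -> Pocket:
    """Binding residues of a holo complex by heavy-atom contact distance.

    A residue belongs to the pocket when any of its heavy atoms lies within
    ``cutoff`` of any ligand heavy atom. The pocket center is the geometric
    center of the ligand's heavy atoms.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_xyz = ligand.heavy_coords()
    rows = []
    for res in structure.residues():
        res_xyz = res.heavy_coords()
        if res_xyz.size == 0:
            continue
        d2 = np.sum(
            (res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=-1
        )
        if np.any(d2 <= cutoff * cutoff):
            ca = res.ca
            ca_xyz = ca.coords if ca is not None else res_xyz.mean(axis=0)
            rows.append(
                (res, ca_xyz, features_for_residue(res.res_name, conservation))
            )
    if not rows:
        raise ValueError(
            f"no residue of {structure.id!r} within {cutoff} Å of ligand {ligand.id!r}"
        )
    return Pocket(
        target_id=structure.id,
        residues=rows,
        center=lig_xyz.mean(axis=0),
        confidence=100.0,
    )


def pocket_from_annotation(
    structure: MolecularStructure,
    annotation: PocketAnnotation,
    conservation: float = 1.0,
) -> Pocket:
    """Build a pocket from a predicted binding-site annotation.

    The center is the annotation's explicit center when given, otherwise the
    centroid of the annotated residues' Cα atoms.
    """
    rows = []
    missing = []
    for chain_id, seq_number, res_name in annotation.residues:
        res = structure.find_residue(chain_id, seq_number)
        if res is None:
            missing.append(f"{chain_id}:{seq_number}:{res_name}")
            continue
        ca = res.ca
        ca_xyz = ca.coords if ca is not None else res.heavy_coords().mean(axis=0)
        rows.append((res, ca_xyz, features_for_residue(res.res_name, conservation)))
    if missing:
        raise ValueError(
            f"annotation {annotation.target_id!r}: unresolvable residue(s) "
            + ", ".join(missing)
        )
    center = (
        annotation.center
        if annotation.center is not None
        else np.asarray([c for _, c, _ in rows]).mean(axis=0)
    )
    return Pocket(
        target_id=annotation.target_id,
        residues=rows,
        center=center,
        confidence=annotation.confidence,
    )


def annotation_is_correct(
    pocket_center: np.ndarray,
    ligand: SmallMolecule,
    threshold: float = CENTER_CORRECT_THRESHOLD,
) -> bool:
    """True when the predicted center is within ``threshold`` Å (inclusive)
    of the bound ligand's geometric center."""
    center = np.asarray(pocket_center, dtype=float)
    return bool(np.linalg.norm(center - ligand.geometric_center()) <= threshold)


def ligand_radius_of_gyration(ligand: SmallMolecule) -> float:
    """Unweighted (geometric) radius of gyration of the heavy atoms, Å."""
    xyz = ligand.heavy_coords()
    if xyz.shape[0] < 2:
        raise ValueError("radius of gyration needs at least 2 heavy atoms")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def search_box_from_rg(rg: float) -> float:
    """Docking search-box edge (Å) from the ligand radius of gyration.

    edge = 2.9 x Rg, floored at 22.5 Å — the published box-optimization rule
    for Vina-style search spaces.
    """
    if rg <= 0:
        raise ValueError("radius of gyration must be positive")
    return max(2.9 * rg, 22.5)


def property_profile(ligands: Sequence[SmallMolecule]) -> LigandProfile:
    """Mean and population SD of MW, logP and PSA over a ligand set."""
    from . import chem

    if not ligands:
        raise ValueError("property_profile needs at least one ligand")
    mw, logp, psa = [], [], []
    for lig in ligands:
        try:
            d = chem.descriptors(lig)
        except Exception as exc:
            raise ValueError(f"descriptor failure on ligand {lig.id!r}: {exc}") from exc
        mw.append(d.mw)
        logp.append(d.logp)
        psa.append(d.tpsa)
    mw, logp, psa = np.asarray(mw), np.asarray(logp), np.asarray(psa)
    return LigandProfile(
        mw_mean=float(mw.mean()), mw_sd=float(mw.std()),
        logp_mean=float(logp.mean()), logp_sd=float(logp.std()),
        psa_mean=float(psa.mean()), psa_sd=float(psa.std()),
    )


def confidence_tier(
    confidence: float, high: float = 80.0, moderate: float = 50.0
) -> str:
    """Map a percent confidence to 'high' / 'moderate' / 'low' tiers.

    Tier boundaries are configurable; the defaults put >= 80% in the high
    tier and >= 50% in the moderate tier.
    """
    if confidence >= high:
        return "high"
    if confidence >= moderate:
        return "moderate"
    return "low"
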