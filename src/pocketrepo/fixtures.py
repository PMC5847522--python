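"""Deterministic synthetic data for every pipeline stage.

Everything here is generated, never downloaded: toy proteins and pockets
with tunable similarity, paired screening rank lists with a plantable rank
correlation and plantable active enrichment, and toy protein-ligand
complexes with a plantable short-range type-pair preference for potential
training. All randomness flows through ``numpy.random.default_rng`` (PCG64)
seeded per generator call, so identical specs produce identical artifacts on
any platform.

Toy "proteins" are Cα+Cβ skeletons plus a couple of side-chain pseudo-atoms
per residue — enough geometry for contacts, clashes, and pocket alignment,
with no pretense of rotamer chemistry. Pocket residues sit on a jittered
sphere of radius 8 Å, roughly the scale of a drug-binding site.

The derived-pocket generator is the study-condition dial for recognition
benchmarks: ``overlap`` controls what fraction of binding residues two
pockets share, and the feature/coordinate noise levels emulate the residue
misannotations and model imperfections that predicted (rather than crystal)
binding sites carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pocketmodel import (
    KYTE_DOOLITTLE,
    Pocket,
    ResidueFeatures,
    features_for_residue,
)
from .structio import AtomRecord, MolecularStructure, Residue, SmallMolecule
from .vsim import RankList, RecognitionCase, rank_list_from_scores

__all__ = [
    "FixtureSpec",
    "make_toy_pocket",
    "derive_similar_pocket",
    "make_screen_library",
    "make_toy_complexes",
    "make_toy_structure",
    "make_toy_ligand",
    "make_recognition_benchmark",
]

POCKET_SPHERE_RADIUS = 8.0  # Å
AMINO_ACIDS = tuple(sorted(KYTE_DOOLITTLE))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic-data draw."""

    seed: int
    n_residues: int = 15
    n_compounds: int = 100
    n_complexes: int = 50
    feature_noise: float = 0.0  # SD of hydropathy jitter (KD units)
    coord_noise: float = 0.0  # SD of Cα jitter (Å)
    overlap: float = 1.0
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")
        if self.n_residues < 5:
            raise ValueError("pockets need >= 5 residues")


def _sphere_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere: Fibonacci lattice plus jitter."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1) * radius
    return pts + rng.normal(scale=0.4, size=pts.shape)


def _make_residue(
    rng: np.random.Generator,
    chain_id: str,
    seq_number: int,
    res_name: str,
    ca: np.ndarray,
) -> Residue:
    """A Cα+Cβ pseudo-residue with up to two side-chain pseudo-atoms."""
    outward = ca / max(np.linalg.norm(ca), 1e-9)
    atoms = [
        AtomRecord(serial=0, name="N", element="N", coords=ca - 1.2 * outward),
        AtomRecord(serial=0, name="CA", element="C", coords=ca.copy()),
        AtomRecord(serial=0, name="C", element="C", coords=ca + 0.8 * outward),
        AtomRecord(serial=0, name="O", element="O", coords=ca + 1.6 * outward),
    ]
    n_side = min(features_for_residue(res_name).side_chain_size, 2)
    for k in range(n_side):
        direction = -outward + rng.normal(scale=0.3, size=3)
        direction /= max(np.linalg.norm(direction), 1e-9)
        atoms.append(
            AtomRecord(
                serial=0,
                name=f"CB{'G'[k:k]}" if k == 0 else "CG",
                coords=ca + 1.5 * (k + 1) * direction,
                element="C",
            )
        )
    return Residue(
        chain_id=chain_id, seq_number=seq_number, res_name=res_name, atoms=atoms
    )


def make_toy_structure(
    spec: FixtureSpec, target_id: Optional[str] = None
) -> MolecularStructure:
    """A toy single-chain protein whose residues ring a central cavity."""
    rng = np.random.default_rng(spec.seed)
    names = rng.choice(AMINO_ACIDS, size=spec.n_residues)
    centers = _sphere_points(rng, spec.n_residues, POCKET_SPHERE_RADIUS)
    residues = [
        _make_residue(rng, "A", i + 1, str(names[i]), centers[i])
        for i in range(spec.n_residues)
    ]
    return MolecularStructure(
        id=target_id or f"toy{spec.seed}", chains={"A": residues}, ligands=[]
    )


def make_toy_pocket(
    spec: FixtureSpec, target_id: Optional[str] = None
) -> tuple[Pocket, MolecularStructure]:
    """A toy pocket: residues on a jittered 8 Å sphere with random features.

    Deterministic under seed; the backing structure is returned alongside so
    contact, clash and transfer operations have real atoms to work with.
    """
    structure = make_toy_structure(spec, target_id=target_id)
    rng = np.random.default_rng((spec.seed, 1))
    rows = []
    for res in structure.chains["A"]:
        # conservation stays at the uninformative 1.0 default: toy pockets
        # carry no evolutionary profile
        rows.append((res, res.ca.coords.copy(), features_for_residue(res.res_name)))
    pocket = Pocket(
        target_id=structure.id,
        residues=rows,
        center=np.zeros(3),
        confidence=float(rng.uniform(80.0, 100.0)),
    )
    return pocket, structure


def _noised_features(
    rng: np.random.Generator, feats: ResidueFeatures, feature_noise: float
) -> ResidueFeatures:
    if feature_noise <= 0:
        return feats
    flip = rng.uniform(size=3) < min(0.5, feature_noise / 4.0)
    return ResidueFeatures(
        hydrophobicity=feats.hydrophobicity + float(rng.normal(scale=feature_noise)),
        charge_class=feats.charge_class if not flip[0] else 0,
        polar=feats.polar ^ bool(flip[1]),
        aromatic=feats.aromatic ^ bool(flip[2]),
        side_chain_size=max(
            0, feats.side_chain_size + int(rng.integers(-1, 2)) * (feature_noise > 0.2)
        ),
        conservation=float(
            np.clip(feats.conservation + rng.normal(scale=feature_noise / 4.0), 0, 1)
        ),
    )


def derive_similar_pocket(
    parent: Pocket,
    overlap: float,
    feature_noise: float = 0.0,
    coord_noise: float = 0.0,
    seed: int = 0,
) -> Pocket:
    """A pocket sharing ``ceil(overlap * n)`` residues with its parent.

    Kept residues are jittered by the noise levels; the rest are replaced by
    fresh random residues placed on the same sphere. With overlap 1 and zero
    noise the derived pocket matches its parent with score 1.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng((seed, 2))
    n = len(parent)
    n_keep = math.ceil(overlap * n)
    rows = []
    for k, (res, ca, feats) in enumerate(parent.residues):
        if k < n_keep:
            new_ca = ca + rng.normal(scale=coord_noise, size=3) if coord_noise > 0 else ca.copy()
            new_feats = _noised_features(rng, feats, feature_noise)
            new_res = Residue(
                chain_id="B", seq_number=k + 1, res_name=res.res_name,
                atoms=[
                    AtomRecord(
                        serial=a.serial, name=a.name, element=a.element,
                        coords=a.coords + (new_ca - ca), occupancy=a.occupancy,
                    )
                    for a in res.atoms
                ],
            )
            rows.append((new_res, new_ca, new_feats))
        else:
            name = str(rng.choice(AMINO_ACIDS))
            ca_new = _sphere_points(rng, 1, POCKET_SPHERE_RADIUS)[0] + rng.normal(
                scale=2.0, size=3
            )
            res_new = _make_residue(rng, "B", k + 1, name, ca_new)
            rows.append((res_new, ca_new, features_for_residue(name)))
    return Pocket(
        target_id=f"{parent.target_id}_d{seed}",
        residues=rows,
        center=parent.center.copy(),
        confidence=parent.confidence,
    )


def make_screen_library(
    n_total: int,
    n_active: int,
    enrichment: float,
    seed: int,
    rho_target: float = 0.8,
) -> tuple[RecognitionCase, RankList, RankList]:
    """A screening library with planted actives and a planted rank correlation.

    Each compound gets a latent affinity; actives receive a score bonus
    proportional to ``enrichment``. Two paired rank lists share signal so
    that their Spearman ρ recovers ``rho_target`` (the Pearson correlation of
    the underlying Gaussians is set to 2 sin(π ρ/6), the exact inverse of
    the Gaussian-copula Spearman relation). Docking convention: lower score
    is better, so actives receive a negative bonus.
    """
    if not (1 <= n_active < n_total):
        raise ValueError("need 1 <= n_active < n_total")
    rng = np.random.default_rng((seed, 3))
    ids = [f"cpd{k:05d}" for k in range(n_total)]
    active = np.zeros(n_total, dtype=bool)
    active[rng.choice(n_total, size=n_active, replace=False)] = True

    r_pearson = float(np.clip(2.0 * math.sin(math.pi * rho_target / 6.0), -1, 1))
    z1 = rng.normal(size=n_total)
    z2 = r_pearson * z1 + math.sqrt(max(1.0 - r_pearson**2, 0.0)) * rng.normal(
        size=n_total
    )
    bonus = enrichment * active
    score1 = z1 - bonus
    score2 = z2 - bonus

    rl1 = rank_list_from_scores("pocketA", dict(zip(ids, score1)))
    rl2 = rank_list_from_scores("pocketB", dict(zip(ids, score2)))
    case = RecognitionCase(
        query_id=f"query{seed}",
        candidates=[
            (cid, -float(s), bool(a)) for cid, s, a in zip(ids, score1, active)
        ],
    )
    return case, rl1, rl2


def make_toy_ligand(
    rng: np.random.Generator,
    n_atoms: int = 8,
    center: Optional[np.ndarray] = None,
    elements: Optional[Sequence[str]] = None,
    spread: float = 1.5,
) -> SmallMolecule:
    """A blob-shaped toy ligand: a random heavy-atom cloud with chain bonds."""
    if center is None:
        center = np.zeros(3)
    if elements is None:
        elements = [str(e) for e in rng.choice(["C", "N", "O"], size=n_atoms, p=[0.7, 0.15, 0.15])]
    coords = center + rng.normal(scale=spread, size=(len(elements), 3))
    atoms = [
        (el, 0, coords[k].copy(), False) for k, el in enumerate(elements)
    ]
    bonds = [(k, k + 1, 1.0) for k in range(len(elements) - 1)]
    return SmallMolecule(id=f"lig{rng.integers(1 << 30)}", atoms=atoms, bonds=bonds)


# Declared planted pair of the training corpus and where it is planted
PLANTED_PROTEIN_TYPE = "bb.C"
PLANTED_LIGAND_TYPE = "O.al"
PLANTED_RANGE = (3.0, 4.0)  # Å


def _reference_distance(rng: np.random.Generator, alpha: float, r_cut: float) -> float:
    """Draw r from the finite ideal-gas reference density pdf(r) ∝ r^α."""
    return float(r_cut * rng.uniform() ** (1.0 / (alpha + 1.0)))


def make_toy_complexes(
    n_complexes: int,
    planted_pair_preference: float,
    seed: int,
    n_protein_residues: int = 4,
    n_ligand_atoms: int = 8,
    alpha: float = 1.61,
    r_cut: float = 14.5,
) -> list[tuple[MolecularStructure, SmallMolecule]]:
    """Toy complexes realizing the r^α reference, with a plantable preference.

    The protein is a sparse Cα-only shell (residues > 2·r_cut apart, so each
    ligand atom sees exactly one protein atom within the cutoff); the ligand
    is a heavy-atom cloud anchored to one residue, with anchor distances
    drawn from the reference density pdf(r) ∝ r^α. The corpus is therefore
    exactly calibrated to the finite ideal-gas reference: with no planted
    preference every trained energy is zero up to counting noise.

    The declared preferred pair is (backbone carbon ``bb.C``, aliphatic
    ligand oxygen ``O.al``): with preference strength p > 0 each ligand
    oxygen is instead placed 3-4 Å from the anchor with probability
    min(p, 1), enriching that pair's short bins against the reference.
    """
    if n_complexes < 1:
        raise ValueError("need >= 1 complex")
    rng = np.random.default_rng((seed, 4))
    spacing = 2.0 * r_cut + 2.0
    p = min(max(planted_pair_preference, 0.0), 1.0)
    out = []
    for k in range(n_complexes):
        # Cα-only residues on a widely spaced line: a minimal "shell" whose
        # atoms never share a ligand atom within r_cut
        residues = []
        positions = []
        names = rng.choice(AMINO_ACIDS, size=n_protein_residues)
        for i in range(n_protein_residues):
            pos = np.array([i * spacing, 0.0, 0.0]) + rng.normal(scale=0.5, size=3)
            positions.append(pos)
            residues.append(
                Residue(
                    chain_id="A",
                    seq_number=i + 1,
                    res_name=str(names[i]),
                    atoms=[AtomRecord(serial=i + 1, name="CA", element="C", coords=pos)],
                )
            )
        structure = MolecularStructure(
            id=f"cplx{seed}_{k}", chains={"A": residues}, ligands=[]
        )
        anchor = positions[int(rng.integers(n_protein_residues))]
        elements = ["C"] * (n_ligand_atoms - 2) + ["O", "O"]
        coords = np.empty((n_ligand_atoms, 3))
        for j, el in enumerate(elements):
            if el == "O" and p > 0 and rng.uniform() < p:
                r = rng.uniform(*PLANTED_RANGE)
            else:
                r = _reference_distance(rng, alpha, r_cut)
            direction = rng.normal(size=3)
            direction /= max(np.linalg.norm(direction), 1e-9)
            coords[j] = anchor + r * direction
        lig = SmallMolecule(
            id=f"lig{seed}_{k}",
            atoms=[(el, 0, coords[j].copy(), False) for j, el in enumerate(elements)],
            bonds=[],
        )
        out.append((structure, lig))
    return out


def make_recognition_benchmark(
    n_queries: int,
    seed: int,
    n_active: int = 4,
    n_decoy: int = 26,
    active_overlap: float = 0.6,
    decoy_overlap: float = 0.45,
    feature_noise: float = 0.25,
    coord_noise: float = 0.8,
    rho_active: float = 0.75,
    rho_decoy: float = 0.0,
    n_library: int = 100,
) -> list[dict]:
    """A pocket-recognition benchmark with overlap-derived actives.

    Each query is a parent pocket; its actives are pockets derived from the
    same parent at high residue overlap (they "bind similar ligands"), its
    decoys at low overlap. Every candidate also carries a screening rank
    list whose correlation with the query's list is planted high for actives
    and null for decoys. Returns one dict per query with the candidate
    pockets, their labels, and their (query rank list, candidate rank list)
    pairs — enough to score recognition by pocket alignment alone, by
    screening correlation, or by their fusion.
    """
    from .pocketalign import match_pockets
    from .vsim import spearman_rho

    rng = np.random.default_rng((seed, 5))
    queries = []
    for q in range(n_queries):
        parent_seed = int(rng.integers(1 << 30))
        parent, _ = make_toy_pocket(FixtureSpec(seed=parent_seed))
        candidates = []
        labels = [True] * n_active + [False] * n_decoy
        for k, is_active in enumerate(labels):
            child = derive_similar_pocket(
                parent,
                overlap=active_overlap if is_active else decoy_overlap,
                feature_noise=feature_noise,
                coord_noise=coord_noise,
                seed=int(rng.integers(1 << 30)),
            )
            _, rl_query, rl_cand = make_screen_library(
                n_library,
                max(1, n_library // 20),
                enrichment=1.0,
                seed=int(rng.integers(1 << 30)),
                rho_target=rho_active if is_active else rho_decoy,
            )
            ems = match_pockets(parent, child).ems_score
            rho = spearman_rho(rl_query, rl_cand).rho
            candidates.append(
                {
                    "id": f"q{q}c{k}",
                    "pocket": child,
                    "is_active": is_active,
                    "ems": ems,
                    "rho": rho,
                }
            )
        queries.append({"query_id": f"q{q}", "parent": parent, "candidates": candidates})
    return queries
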