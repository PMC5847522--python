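"""Distance-scaled finite ideal-gas reference (DFIRE-style) statistical potential.

Knowledge-based protein-ligand energies are extracted from an ensemble of
complexes: observed heavy-atom pair counts N(i, j, r) in distance bins are
compared against a finite ideal-gas reference state in which the expected
count grows as r^α (α = 1.61, the distance-scaling exponent of the finite
system) up to a cutoff r_cut where the interaction is taken to vanish:

    u(i, j, r) = -η · ln[ (N(i,j,r) + q) /
                          ((r / r_cut)^α · (Δr / Δr_cut) · (N(i,j,r_cut bin) + q)) ]

evaluated at bin centers, with pseudocount q keeping every entry defined.
Energies are in arbitrary units (η = 1): only signs and orderings are
contract-bearing — a pair type observed in excess at short range against the
reference scores negative (favorable). A complex is scored by summing
u over all protein-ligand heavy-atom pairs within r_cut; lower is more
favorable, and the score is invariant under rigid motions applied jointly to
protein and pose.

Default binning: 0.5 Å bins up to r_cut = 14.5 Å. Protein atoms are typed by
backbone/side-chain role and element; ligand atoms by (element, aromaticity)
— a coarse scheme frugal enough for small training corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .structio import MolecularStructure, SmallMolecule

__all__ = [
    "AtomTyping",
    "DistanceBinning",
    "PotentialTable",
    "default_typing",
    "default_binning",
    "count_contacts",
    "train_potential",
    "score_complex",
    "compare_source_destination",
]

ALPHA = 1.61
R_CUT = 14.5
BIN_WIDTH = 0.5

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class AtomTyping:
    """Maps protein atoms and ligand atoms onto a joint type alphabet."""

    protein_types: tuple[str, ...]
    ligand_types: tuple[str, ...]

    @property
    def n_protein(self) -> int:
        return len(self.protein_types)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_types)

    def protein_type(self, res_name: str, atom_name: str, element: str) -> int:
        """Type id of a protein heavy atom; unknown atoms hit the catch-all."""
        el = element.upper()
        if atom_name.upper() in _BACKBONE:
            label = f"bb.{el}"
        else:
            label = f"sc.{el}"
        try:
            return self.protein_types.index(label)
        except ValueError:
            return len(self.protein_types) - 1  # catch-all

    def ligand_type(self, element: str, aromatic: bool) -> int:
        label = f"{element.upper()}.{'ar' if aromatic else 'al'}"
        try:
            return self.ligand_types.index(label)
        except ValueError:
            return len(self.ligand_types) - 1


def default_typing() -> AtomTyping:
    protein = (
        "bb.N", "bb.C", "bb.O",
        "sc.C", "sc.N", "sc.O", "sc.S",
        "other",
    )
    ligand = (
        "C.al", "C.ar", "N.al", "N.ar", "O.al", "O.ar",
        "S.al", "P.al", "HAL.al",  # halogens pooled
        "other",
    )
    return AtomTyping(protein_types=protein, ligand_types=ligand)


_HALOGENS = {"F", "CL", "BR", "I"}


def _ligand_label_element(element: str) -> str:
    el = element.upper()
    return "HAL" if el in _HALOGENS else el


@dataclass(frozen=True)
class DistanceBinning:
    """Half-open distance bins [e_k, e_{k+1}) ending at r_cut."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def r_cut(self) -> float:
        return self.edges[-1]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges))

    def bin_of(self, distances: np.ndarray) -> np.ndarray:
        """Bin index per distance; -1 for distances outside [e0, r_cut)."""
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.edges, d, side="right") - 1
        idx[(d < self.edges[0]) | (d >= self.r_cut)] = -1
        return idx


def default_binning(r_cut: float = R_CUT, width: float = BIN_WIDTH) -> DistanceBinning:
    n = int(round(r_cut / width))
    return DistanceBinning(edges=tuple(np.round(np.arange(n + 1) * width, 10)))


@dataclass
class PotentialTable:
    """Trained atom-pair energies u(i, j, bin) with their typing and binning."""

    u: np.ndarray  # (n_protein, n_ligand, n_bins)
    typing: AtomTyping
    binning: DistanceBinning
    alpha: float = ALPHA
    eta: float = 1.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        expect = (self.typing.n_protein, self.typing.n_ligand, self.binning.n_bins)
        if self.u.shape != expect:
            raise ValueError(f"u must have shape {expect}, got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("potential table contains non-finite energies")

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "alpha": self.alpha,
            "eta": self.eta,
            "edges": list(self.binning.edges),
            "protein_types": list(self.typing.protein_types),
            "ligand_types": list(self.typing.ligand_types),
            "u": self.u.tolist(),
        }
        Path(path).write_text(json.dumps(payload))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "PotentialTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            u=np.asarray(payload["u"]),
            typing=AtomTyping(
                protein_types=tuple(payload["protein_types"]),
                ligand_types=tuple(payload["ligand_types"]),
            ),
            binning=DistanceBinning(edges=tuple(payload["edges"])),
            alpha=payload["alpha"],
            eta=payload["eta"],
        )


def _pair_types_and_distances(
    structure: MolecularStructure,
    pose: SmallMolecule,
    typing: AtomTyping,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Protein type ids, ligand type ids, and the distance matrix (Å)."""
    p_xyz, refs = structure.protein_heavy_atoms()
    p_types = np.array(
        [typing.protein_type(res.res_name, a.name, a.element) for res, a in refs],
        dtype=int,
    )
    l_xyz = pose.heavy_coords()
    l_types = np.array(
        [
            typing.ligand_type(_ligand_label_element(el), ar)
            for el, ar in zip(pose.heavy_elements(), pose.heavy_aromatic_flags())
        ],
        dtype=int,
    )
    d = np.sqrt(
        np.sum((p_xyz[:, None, :] - l_xyz[None, :, :]) ** 2, axis=-1)
    )
    return p_types, l_types, d


def count_contacts(
    complexes: Sequence[tuple[MolecularStructure, SmallMolecule]],
    typing: Optional[AtomTyping] = None,
    binning: Optional[DistanceBinning] = None,
) -> np.ndarray:
    """Observed pair counts N(i, j, bin) over a complex ensemble.

    Every protein-heavy/ligand-heavy atom pair contributes to the bin of its
    distance; pairs at or beyond r_cut are ignored (half-open binning).
    """
    if not complexes:
        raise ValueError("empty complex list")
    typing = typing or default_typing()
    binning = binning or default_binning()
    counts = np.zeros((typing.n_protein, typing.n_ligand, binning.n_bins))
    for structure, pose in complexes:
        p_types, l_types, d = _pair_types_and_distances(structure, pose, typing)
        bins = binning.bin_of(d.ravel())
        mask = bins >= 0
        pi = np.repeat(p_types, len(l_types))[mask]
        lj = np.tile(l_types, len(p_types))[mask]
        np.add.at(counts, (pi, lj, bins[mask]), 1.0)
    return counts


def train_potential(
    counts: np.ndarray,
    typing: Optional[AtomTyping] = None,
    binning: Optional[DistanceBinning] = None,
    alpha: float = ALPHA,
    eta: float = 1.0,
    pseudocount: float = 1.0,
) -> PotentialTable:
    """Convert pair counts into energies against the r^α reference state.

    The last (r_cut) bin anchors the reference: u there is 0 by
    construction. The pseudocount keeps every entry defined for sparse
    corpora; with pseudocount 0 and counts exactly proportional to the
    reference, u is identically 0.
    """
    typing = typing or default_typing()
    binning = binning or default_binning()
    counts = np.asarray(counts, dtype=float)
    centers = binning.centers
    widths = binning.widths
    r_cut_center = centers[-1]
    ref_shape = (centers / r_cut_center) ** alpha * (widths / widths[-1])
    n_ref = counts[:, :, -1][:, :, None] + pseudocount  # (i, j, 1)
    observed = counts + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed / (ref_shape[None, None, :] * n_ref)
        u = -eta * np.log(ratio)
    u[~np.isfinite(u)] = 0.0  # pairs never observed anywhere (pseudocount 0)
    return PotentialTable(u=u, typing=typing, binning=binning, alpha=alpha, eta=eta)


def score_complex(
    structure: MolecularStructure,
    pose: SmallMolecule,
    table: PotentialTable,
) -> float:
    """Total pairwise energy of a complex; lower is more favorable."""
    p_types, l_types, d = _pair_types_and_distances(structure, pose, table.typing)
    bins = table.binning.bin_of(d.ravel())
    mask = bins >= 0
    if not np.any(mask):
        return 0.0
    pi = np.repeat(p_types, len(l_types))[mask]
    lj = np.tile(l_types, len(p_types))[mask]
    return float(np.sum(table.u[pi, lj, bins[mask]]))


def compare_source_destination(
    records: Sequence[tuple[float, Sequence[float]]],
) -> dict:
    """Correlate source-complex energies with mean destination energies.

    Each record is (source energy, destination energies of the same drug).
    Returns the Pearson correlation, the regression slope/intercept, and the
    standard error of each destination mean.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records")
    x = np.array([r[0] for r in records], dtype=float)
    means = np.array([np.mean(r[1]) for r in records])
    sems = np.array(
        [
            (np.std(r[1], ddof=1) / np.sqrt(len(r[1]))) if len(r[1]) > 1 else 0.0
            for r in records
        ]
    )
    if np.std(x) == 0 or np.std(means) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    reg = stats.linregress(x, means)
    return {
        "pearson_r": float(reg.rvalue),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "sem_destination": sems,
        "n": len(records),
    }
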