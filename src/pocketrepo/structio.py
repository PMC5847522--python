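"""Molecular structure I/O and the core structural data model.

Reads and writes the plain-text formats the repositioning pipeline touches:
PDB structures (via gemmi), SDF/SMILES small molecules (via RDKit, see
:mod:`pocketrepo.chem`), and the tabular pocket-annotation format.

Conventions: coordinates are Å throughout; author residue numbering is kept
(no renumbering); residue identity is the triple (chain, seq_number,
insertion_code). Hetero groups with fewer than 4 heavy atoms, and all
waters, are never treated as ligands — this excludes ions and buffer
components and matches the drug-size regime (MW 150-550 Da) the pipeline
targets. Alternate locations keep the highest-occupancy conformer (first on
tie).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Residue",
    "SmallMolecule",
    "MolecularStructure",
    "PocketAnnotation",
    "StructureParseError",
    "read_pdb",
    "write_pdb",
    "write_complex",
    "read_small_molecule",
    "read_pocket_annotations",
    "write_pocket_annotations",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
MIN_LIGAND_HEAVY_ATOMS = 4

_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "Y", "ZR", "MO", "RU", "RH", "PD", "AG", "CD", "IN", "SN", "SB", "TE",
    "I", "XE", "CS", "BA", "W", "PT", "AU", "HG", "TL", "PB", "BI", "U",
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


@dataclass
class AtomRecord:
    """One heavy (or hydrogen) atom from an ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if self.element.upper() not in _ELEMENTS:
            raise ValueError(f"atom {self.name!r}: unknown element {self.element!r}")


@dataclass
class Residue:
    """A residue keyed by (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: Optional[str] = None

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.key}: duplicate atom names after altloc resolution"
            )

    @property
    def key(self) -> tuple[str, int, Optional[str]]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[AtomRecord]:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.element.upper() != "H"]
        return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass
class SmallMolecule:
    """A small-molecule graph, optionally with 3D coordinates.

    ``atoms`` holds (element, formal_charge, coords-or-None, aromatic) tuples;
    ``bonds`` holds (i, j, order). SMILES-derived molecules carry no
    coordinates and are only valid for descriptor/fingerprint work.
    """

    id: str
    atoms: list[tuple[str, int, Optional[np.ndarray], bool]]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    name: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if self.n_heavy_atoms < 1:
            raise ValueError(f"molecule {self.id!r}: needs at least one heavy atom")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id!r}: bond ({i},{j}) out of range")
        with_c = [a for a in self.atoms if a[2] is not None and a[0].upper() != "H"]
        heavy = [a for a in self.atoms if a[0].upper() != "H"]
        if with_c and len(with_c) != len(heavy):
            raise ValueError(
                f"molecule {self.id!r}: coordinates must cover all heavy atoms or none"
            )

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a[0].upper() != "H")

    @property
    def has_coords(self) -> bool:
        heavy = [a for a in self.atoms if a[0].upper() != "H"]
        return bool(heavy) and all(a[2] is not None for a in heavy)

    def heavy_coords(self) -> np.ndarray:
        """Heavy-atom coordinates in atom order, (n_heavy, 3) Å."""
        if not self.has_coords:
            raise ValueError(f"molecule {self.id!r}: no 3D coordinates")
        return np.asarray(
            [a[2] for a in self.atoms if a[0].upper() != "H"], dtype=float
        )

    def heavy_elements(self) -> list[str]:
        return [a[0] for a in self.atoms if a[0].upper() != "H"]

    def heavy_aromatic_flags(self) -> list[bool]:
        return [a[3] for a in self.atoms if a[0].upper() != "H"]

    def geometric_center(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)

    def with_coords(self, coords: np.ndarray, id: Optional[str] = None) -> "SmallMolecule":
        """Copy of this molecule with heavy-atom coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        heavy_idx = [k for k, a in enumerate(self.atoms) if a[0].upper() != "H"]
        if coords.shape != (len(heavy_idx), 3):
            raise ValueError("coords shape must be (n_heavy, 3)")
        atoms = list(self.atoms)
        for row, k in enumerate(heavy_idx):
            el, q, _, arom = atoms[k]
            atoms[k] = (el, q, coords[row].copy(), arom)
        return SmallMolecule(
            id=id or self.id, atoms=atoms, bonds=list(self.bonds), name=self.name
        )


@dataclass
class MolecularStructure:
    """A protein structure: ordered residues per chain plus extracted ligands."""

    id: str
    chains: dict[str, list[Residue]]
    ligands: list[SmallMolecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [(r.seq_number, r.insertion_code) for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"chain {cid}: duplicate residue identifiers")

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for cid in self.chains:
            out.extend(self.chains[cid])
        return out

    def find_residue(
        self, chain_id: str, seq_number: int, insertion_code: Optional[str] = None
    ) -> Optional[Residue]:
        for r in self.chains.get(chain_id, []):
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def protein_heavy_atoms(self) -> tuple[np.ndarray, list[tuple[Residue, AtomRecord]]]:
        """All protein heavy atoms as (coords array, (residue, atom) refs)."""
        refs: list[tuple[Residue, AtomRecord]] = []
        for res in self.residues():
            for a in res.atoms:
                if a.element.upper() != "H":
                    refs.append((res, a))
        coords = np.asarray([a.coords for _, a in refs], dtype=float).reshape(-1, 3)
        return coords, refs

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def sequence(self, chain_id: Optional[str] = None) -> str:
        chains = [chain_id] if chain_id else list(self.chains)
        return "".join(
            _THREE_TO_ONE.get(r.res_name, "X")
            for c in chains
            for r in self.chains[c]
        )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class PocketAnnotation:
    """A predicted binding site: residue list plus prediction confidence (%)."""

    target_id: str
    residues: list[tuple[str, int, str]]  # (chain_id, seq_number, res_name)
    confidence: float
    center: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"annotation {self.target_id!r}: empty residue list")
        if not (0.0 <= self.confidence <= 100.0):
            raise ValueError(
                f"annotation {self.target_id!r}: confidence {self.confidence} "
                "outside [0, 100]"
            )
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)


# ---------------------------------------------------------------------------
# PDB reading


def _resolve_altlocs(atom_groups: dict[str, list]) -> list:
    """Keep the highest-occupancy conformer per atom name (first on tie)."""
    kept = []
    for _, group in atom_groups.items():
        best = max(group, key=lambda a: a.occ)  # max() keeps first on ties
        kept.append(best)
    return kept


def read_pdb(path: str | Path, structure_id: Optional[str] = None) -> MolecularStructure:
    """Read a PDB file into a :class:`MolecularStructure`.

    Hetero groups with >= 4 heavy atoms (waters excluded) are exposed as
    ligands; smaller hetero groups (ions, buffers) are dropped. Only the
    first MODEL of a multi-model file is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise StructureParseError(f"{path}: {exc}") from exc
    _validate_fixed_width(path)
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models/atoms found")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    ligands: list[SmallMolecule] = []
    serial = 0
    n_raw_atoms = 0
    for chain in model:
        for res in chain:
            n_raw_atoms += len(res)
            atom_groups: dict[str, list] = {}
            for atom in res:
                atom_groups.setdefault(atom.name, []).append(atom)
            kept = _resolve_altlocs(atom_groups)
            records = []
            for atom in kept:
                serial += 1
                records.append(
                    AtomRecord(
                        serial=atom.serial or serial,
                        name=atom.name,
                        element=atom.element.name if atom.element.name else "C",
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        is_hetero=res.het_flag == "H",
                    )
                )
            is_het = res.het_flag == "H" and res.name not in _THREE_TO_ONE
            if is_het:
                if res.name in WATER_NAMES:
                    continue
                heavy = [a for a in records if a.element.upper() != "H"]
                if len(heavy) < MIN_LIGAND_HEAVY_ATOMS:
                    continue
                ligands.append(
                    SmallMolecule(
                        id=f"{res.name}_{chain.name}_{res.seqid.num}",
                        atoms=[
                            (a.element, 0, a.coords.copy(), False) for a in heavy
                        ],
                        bonds=[],
                        name=res.name,
                    )
                )
            else:
                chains.setdefault(chain.name, []).append(
                    Residue(
                        chain_id=chain.name,
                        seq_number=res.seqid.num,
                        res_name=res.name,
                        atoms=records,
                        insertion_code=(res.seqid.icode.strip() or None),
                    )
                )
    if n_raw_atoms == 0:
        raise StructureParseError(f"{path}: structure contains no atoms")
    return MolecularStructure(
        id=structure_id or path.stem, chains=chains, ligands=ligands
    )


def _validate_fixed_width(path: Path) -> None:
    """Reject coordinate records whose fixed-width fields are not numeric."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise StructureParseError(
                            f"{path}, line {lineno}: malformed coordinate field "
                            f"{line[lo:hi]!r}"
                        ) from None


# ---------------------------------------------------------------------------
# PDB writing


def _to_gemmi(
    structure: MolecularStructure,
    poses: Sequence[SmallMolecule] = (),
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id

    def build_model(name: str, pose: Optional[SmallMolecule]) -> gemmi.Model:
        model = gemmi.Model(name)
        serial = 0
        for cid, residues in structure.chains.items():
            chain = gemmi.Chain(cid)
            for res in residues:
                g = gemmi.Residue()
                g.name = res.res_name
                g.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
                g.het_flag = "A"
                for a in res.atoms:
                    serial += 1
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.serial = serial
                    g.add_atom(ga)
                chain.add_residue(g)
            model.add_chain(chain)
        lig_sources = [pose] if pose is not None else list(structure.ligands)
        if lig_sources:
            lig_chain = gemmi.Chain("X")
            for li, lig in enumerate(lig_sources, start=1):
                g = gemmi.Residue()
                g.name = (lig.name or "LIG")[:3].upper() or "LIG"
                g.seqid = gemmi.SeqId(li, " ")
                g.het_flag = "H"
                elements = lig.heavy_elements()
                coords = lig.heavy_coords()
                counts: dict[str, int] = {}
                for el, xyz in zip(elements, coords):
                    serial += 1
                    counts[el] = counts.get(el, 0) + 1
                    ga = gemmi.Atom()
                    ga.name = f"{el.upper()}{counts[el]}"
                    ga.element = gemmi.Element(el)
                    ga.pos = gemmi.Position(*xyz)
                    ga.occ = 1.0
                    ga.serial = serial
                    g.add_atom(ga)
                lig_chain.add_residue(g)
            model.add_chain(lig_chain)
        return model

    if len(poses) > 1:
        for mi, pose in enumerate(poses, start=1):
            st.add_model(build_model(str(mi), pose))
    else:
        st.add_model(build_model("1", poses[0] if poses else None))
    return st


def write_pdb(structure: MolecularStructure, path: str | Path) -> Path:
    """Write a structure (protein ATOM records + ligand HETATM records)."""
    path = Path(path)
    st = _to_gemmi(structure)
    st.write_pdb(str(path))
    return path


def write_complex(
    structure: MolecularStructure,
    pose: SmallMolecule | Sequence[SmallMolecule],
    path: str | Path,
) -> Path:
    """Write a protein-ligand complex as a single PDB file.

    One pose writes a single model; several poses of the same drug write
    MODEL/ENDMDL blocks, one per pose. The output is re-readable by
    :func:`read_pdb` with the same ligand partition.
    """
    poses = [pose] if isinstance(pose, SmallMolecule) else list(pose)
    if not poses:
        raise ValueError("write_complex: no pose given")
    for p in poses:
        if not p.has_coords:
            raise ValueError(f"pose {p.id!r} lacks 3D coordinates")
    path = Path(path)
    st = _to_gemmi(structure, poses=poses)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Small molecules (delegates to chem's RDKit bridge)


def read_small_molecule(path_or_smiles: str | Path, id: Optional[str] = None) -> SmallMolecule:
    """Read an SDF file (first record) or parse a SMILES string.

    SMILES input yields a molecular graph without coordinates, suitable for
    descriptor and fingerprint work only.
    """
    from . import chem  # local import: chem depends on this module's types

    text = str(path_or_smiles)
    if text.lower().endswith(".sdf") or Path(text).exists():
        return chem.mol_from_sdf(Path(text), id=id)
    return chem.mol_from_smiles(text, id=id)


# ---------------------------------------------------------------------------
# Pocket-annotation TSV

ANNOTATION_COLUMNS = ["target_id", "chain", "resnum", "resname", "confidence"]


def read_pocket_annotations(path: str | Path) -> list[PocketAnnotation]:
    """Read the pocket-annotation TSV (one row per binding residue).

    Required columns: target_id, chain, resnum, resname, confidence.
    Rows sharing a target_id form one annotation; residue order is kept.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    unknown = set(df.columns) - set(ANNOTATION_COLUMNS)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {sorted(unknown)}")
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("target_id", sort=False):
        conf = grp["confidence"].to_numpy(dtype=float)
        if not np.all((conf >= 0) & (conf <= 100)):
            raise ValueError(f"{path}: confidence outside [0, 100] for {tid!r}")
        out.append(
            PocketAnnotation(
                target_id=str(tid),
                residues=[
                    (str(r.chain), int(r.resnum), str(r.resname))
                    for r in grp.itertuples()
                ],
                confidence=float(conf[0]),
            )
        )
    return out


def write_pocket_annotations(annotations: Iterable[PocketAnnotation], path: str | Path) -> Path:
    rows = []
    for ann in annotations:
        for chain, resnum, resname in ann.residues:
            rows.append(
                {
                    "target_id": ann.target_id,
                    "chain": chain,
                    "resnum": resnum,
                    "resname": resname,
                    "confidence": ann.confidence,
                }
            )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)
    return Path(path)
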