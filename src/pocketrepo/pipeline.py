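"""End-to-end drug-repositioning orchestration.

The run mirrors a source-library -> destination-library repositioning
campaign: filter drugs (MW 150-550 Da), targets (50-999 residues, model
GDT >= 0.4) and pockets (confidence tier), remove redundancy (ligand
Tanimoto 0.9, protein sequence identity 0.80), match every surviving source
pocket against every destination pocket, and for each significant alignment
transfer every drug bound to the source, relieve clashes, score both ends
with the statistical potential, and catalog the result. One alignment can
yield many records (several drugs on one source) and one drug-destination
pair can be reached through several sources, in which case the catalog row
carries all provenance routes plus a consensus-pose report.

Every filter decision is logged as a JSON line; the whole run is a pure
function of its inputs and configuration (byte-identical on re-run).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chem
from .pocketalign import SIGNIFICANCE_THRESHOLD, match_pockets
from .pocketmodel import Pocket, confidence_tier
from .potential import PotentialTable, score_complex
from .reposition import (
    CLASH_CUTOFF,
    DrugPose,
    consensus_pose,
    detect_clashes,
    relieve_clashes,
    transfer_by_alignment,
)
from .structio import MolecularStructure, SmallMolecule

__all__ = [
    "RepositionConfig",
    "RepositioningRecord",
    "apply_filters",
    "deduplicate",
    "run_repositioning",
    "export_catalog",
    "read_catalog",
]


@dataclass(frozen=True)
class RepositionConfig:
    """Thresholds of the repositioning funnel (all inclusive bounds)."""

    drug_mw_min: float = 150.0
    drug_mw_max: float = 550.0
    protein_len_min: int = 50
    protein_len_max: int = 999
    min_gdt: float = 0.4
    required_tier: str = "moderate"  # 'high' accepts only high; 'moderate' accepts both
    ems_threshold: float = SIGNIFICANCE_THRESHOLD
    ligand_tc_threshold: float = 0.9
    protein_identity_threshold: float = 0.80
    clash_cutoff: float = CLASH_CUTOFF
    tier_high: float = 80.0
    tier_moderate: float = 50.0

    def __post_init__(self) -> None:
        if self.drug_mw_min > self.drug_mw_max:
            raise ValueError("drug MW range is reversed")
        if self.protein_len_min > self.protein_len_max:
            raise ValueError("protein length range is reversed")
        for name in ("min_gdt", "ems_threshold", "ligand_tc_threshold",
                     "protein_identity_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.required_tier not in ("high", "moderate", "low"):
            raise ValueError("required_tier must be high/moderate/low")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RepositionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return Path(path)


@dataclass
class RepositioningRecord:
    """One drug proposed for one destination target."""

    drug_id: str
    source_target_id: str  # primary (first) source route
    destination_target_id: str
    ems: float
    rho: Optional[float]
    combined: Optional[float]
    dfire_source: Optional[float]
    dfire_destination: Optional[float]
    n_aligned: int
    aligned_rmsd: float
    residual_clashes: int
    provenance: list[str] = field(default_factory=list)
    consensus_spread: Optional[float] = None
    disease_refs: list[str] = field(default_factory=list)


class _JsonlLog:
    def __init__(self) -> None:
        self.events: list[dict] = []

    def log(self, **event) -> None:
        self.events.append(event)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")


def apply_filters(
    drugs: dict[str, SmallMolecule],
    targets: dict[str, MolecularStructure],
    pockets: dict[str, Pocket],
    config: RepositionConfig,
    gdt: Optional[dict[str, float]] = None,
    mw: Optional[dict[str, float]] = None,
    log: Optional[_JsonlLog] = None,
) -> tuple[dict, dict, dict, list[dict]]:
    """Apply the MW / length / GDT / confidence-tier filter cascade.

    ``gdt`` and ``mw`` supply per-id metadata (model quality estimates,
    tabulated molecular weights); MW is computed from the molecule when not
    given, and a missing GDT estimate passes the model-quality gate. Returns
    the surviving drugs, targets, pockets and the exclusion log (every
    exclusion carries its reason). Boundary values survive: a drug of
    exactly 150 or 550 Da, a protein of exactly 50 or 999 residues, and a
    model of exactly the GDT threshold are all kept.
    """
    log = log or _JsonlLog()
    excluded: list[dict] = []

    def drop(kind: str, item_id: str, reason: str, value) -> None:
        entry = {"kind": kind, "id": item_id, "reason": reason, "value": value}
        excluded.append(entry)
        log.log(event="exclude", **entry)

    kept_drugs = {}
    for did in sorted(drugs):
        mw_val = (mw or {}).get(did)
        if mw_val is None:
            mw_val = chem.molecular_weight(drugs[did])
        if mw_val < config.drug_mw_min:
            drop("drug", did, "mw_below_range", mw_val)
        elif mw_val > config.drug_mw_max:
            drop("drug", did, "mw_above_range", mw_val)
        else:
            kept_drugs[did] = drugs[did]

    kept_targets = {}
    for tid in sorted(targets):
        n = targets[tid].n_residues
        if n < config.protein_len_min:
            drop("target", tid, "length_below_range", n)
            continue
        if n > config.protein_len_max:
            drop("target", tid, "length_above_range", n)
            continue
        g = (gdt or {}).get(tid, 1.0)
        if g < config.min_gdt:
            drop("target", tid, "gdt_below_threshold", g)
            continue
        kept_targets[tid] = targets[tid]

    tier_order = {"high": 2, "moderate": 1, "low": 0}
    required = tier_order[config.required_tier]
    kept_pockets = {}
    for pid in sorted(pockets):
        pocket = pockets[pid]
        if pocket.target_id not in kept_targets:
            drop("pocket", pid, "target_excluded", pocket.target_id)
            continue
        tier = confidence_tier(
            pocket.confidence, high=config.tier_high, moderate=config.tier_moderate
        )
        if tier_order[tier] < required:
            drop("pocket", pid, "confidence_tier_too_low", pocket.confidence)
            continue
        kept_pockets[pid] = pocket
    return kept_drugs, kept_targets, kept_pockets, excluded


def _protein_identity(a: MolecularStructure, b: MolecularStructure) -> float:
    """Global-alignment sequence identity over the shorter sequence."""
    from Bio import Align

    sa, sb = a.sequence(), b.sequence()
    if not sa or not sb:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aln = aligner.align(sa, sb)[0]
    ident = sum(
        1
        for x, y in zip(str(aln[0]), str(aln[1]))
        if x == y and x != "-"
    )
    return ident / min(len(sa), len(sb))


def deduplicate(
    drugs: dict[str, SmallMolecule],
    targets: dict[str, MolecularStructure],
    config: RepositionConfig,
    log: Optional[_JsonlLog] = None,
) -> tuple[dict, dict, dict[str, list[str]]]:
    """Greedy redundancy removal at the configured thresholds.

    Drugs cluster when fingerprint Tanimoto > threshold (strict: TC exactly
    at the threshold keeps both); targets when global sequence identity over
    the shorter chain > threshold. The first member by id becomes the
    cluster representative; membership is returned and logged.
    """
    log = log or _JsonlLog()
    clusters: dict[str, list[str]] = {}

    kept_drugs: dict[str, SmallMolecule] = {}
    fps: dict[str, chem.Fingerprint] = {}
    for did in sorted(drugs):
        fp = chem.fingerprint(drugs[did])
        rep = next(
            (
                r
                for r in kept_drugs
                if chem.tanimoto(fp, fps[r]) > config.ligand_tc_threshold
            ),
            None,
        )
        if rep is None:
            kept_drugs[did] = drugs[did]
            fps[did] = fp
            clusters[f"drug:{did}"] = [did]
        else:
            clusters[f"drug:{rep}"].append(did)
            log.log(event="dedup", kind="drug", id=did, representative=rep)

    kept_targets: dict[str, MolecularStructure] = {}
    for tid in sorted(targets):
        rep = next(
            (
                r
                for r in kept_targets
                if _protein_identity(targets[tid], kept_targets[r])
                > config.protein_identity_threshold
            ),
            None,
        )
        if rep is None:
            kept_targets[tid] = targets[tid]
            clusters[f"target:{tid}"] = [tid]
        else:
            clusters[f"target:{rep}"].append(tid)
            log.log(event="dedup", kind="target", id=tid, representative=rep)
    return kept_drugs, kept_targets, clusters


def run_repositioning(
    source_pockets: dict[str, Pocket],
    source_structures: dict[str, MolecularStructure],
    source_poses: dict[str, list[DrugPose]],
    destination_pockets: dict[str, Pocket],
    destination_structures: dict[str, MolecularStructure],
    config: RepositionConfig = RepositionConfig(),
    table: Optional[PotentialTable] = None,
    rank_lists: Optional[dict[str, "object"]] = None,
    log: Optional[_JsonlLog] = None,
) -> list[RepositioningRecord]:
    """All-against-all matching followed by transfer, refinement and scoring.

    ``source_poses`` maps source target id -> drug poses bound there. For
    every significant source-destination pocket match, every drug bound to
    the source is transferred (one alignment, many records), clash-relieved
    and scored. A drug reaching one destination via several sources becomes
    a single record with all routes in its provenance and the consensus
    spread of its poses.
    """
    from .vsim import combine_scores, spearman_rho

    log = log or _JsonlLog()
    by_pair: dict[tuple[str, str], list[tuple[RepositioningRecord, DrugPose]]] = {}

    for sid in sorted(source_pockets):
        for did in sorted(destination_pockets):
            result = match_pockets(
                source_pockets[sid],
                destination_pockets[did],
                threshold=config.ems_threshold,
            )
            log.log(
                event="match",
                source=sid,
                destination=did,
                ems=round(result.ems_score, 6),
                significant=result.significant,
            )
            if not result.significant:
                continue
            rho = combined = None
            if rank_lists and sid in rank_lists and did in rank_lists:
                rho = spearman_rho(rank_lists[sid], rank_lists[did]).rho
                combined = combine_scores(result.ems_score, rho)
            dest_structure = destination_structures[
                destination_pockets[did].target_id
            ]
            for pose in source_poses.get(sid, []):
                moved = transfer_by_alignment(
                    pose, result.alignment, destination_id=did,
                    alignment_id=f"{sid}->{did}",
                )
                refined, residual = relieve_clashes(
                    moved, dest_structure, clash_cutoff=config.clash_cutoff
                )
                dfire_src = dfire_dst = None
                if table is not None:
                    src_structure = source_structures[
                        source_pockets[sid].target_id
                    ]
                    dfire_src = score_complex(src_structure, pose.drug, table)
                    dfire_dst = score_complex(dest_structure, refined.drug, table)
                rec = RepositioningRecord(
                    drug_id=pose.drug.id,
                    source_target_id=sid,
                    destination_target_id=did,
                    ems=result.ems_score,
                    rho=rho,
                    combined=combined,
                    dfire_source=dfire_src,
                    dfire_destination=dfire_dst,
                    n_aligned=result.alignment.n_aligned,
                    aligned_rmsd=result.alignment.aligned_rmsd,
                    residual_clashes=len(residual),
                    provenance=[f"{sid}->{did}"],
                )
                by_pair.setdefault((pose.drug.id, did), []).append((rec, refined))

    records: list[RepositioningRecord] = []
    for (drug_id, did), items in sorted(by_pair.items()):
        items.sort(key=lambda it: it[0].source_target_id)
        rec = items[0][0]
        rec.provenance = [r.provenance[0] for r, _ in items]
        if len(items) > 1:
            consensus = consensus_pose([p for _, p in items])
            rec.consensus_spread = float(consensus.spread[consensus.typical_index])
            best = items[consensus.typical_index][0]
            rec.source_target_id = best.source_target_id
            rec.ems = best.ems
            rec.rho, rec.combined = best.rho, best.combined
            rec.dfire_source = best.dfire_source
            rec.dfire_destination = best.dfire_destination
            rec.n_aligned, rec.aligned_rmsd = best.n_aligned, best.aligned_rmsd
            rec.residual_clashes = best.residual_clashes
        records.append(rec)
    return records


CATALOG_COLUMNS = [
    "drug_id", "source_target_id", "destination_target_id", "ems", "rho",
    "combined", "dfire_source", "dfire_destination", "n_aligned",
    "aligned_rmsd", "residual_clashes", "provenance", "consensus_spread",
    "disease_refs",
]


def export_catalog(
    records: Sequence[RepositioningRecord], path: str | Path
) -> tuple[Path, Path]:
    """Write the catalog as TSV and JSON with a deterministic column order.

    ``path`` is the TSV path; the JSON sits next to it with suffix .json.
    Round-tripping through :func:`read_catalog` reproduces the records.
    """
    path = Path(path)
    rows = []
    for rec in records:
        row = asdict(rec)
        row["provenance"] = ";".join(rec.provenance)
        row["disease_refs"] = ";".join(rec.disease_refs)
        rows.append(row)
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    json_path = path.with_suffix(".json")
    json_path.write_text(
        json.dumps([asdict(r) for r in records], sort_keys=True, indent=1)
    )
    return path, json_path


def read_catalog(path: str | Path) -> list[RepositioningRecord]:
    """Read a catalog back from its JSON form."""
    payload = json.loads(Path(path).with_suffix(".json").read_text())
    return [RepositioningRecord(**row) for row in payload]
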