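"""Sequence-order-independent binding-pocket alignment and similarity.

Two pockets are compared without regard to chain order: a residue-residue
similarity matrix built from physicochemical features is solved as an
optimal assignment (Kuhn-Munkres), the resulting pairing is pruned to a
geometrically consistent core by iterated Kabsch superposition, and the
final similarity (the eMS-like score) combines the retained pair
similarities with the quality of the local superposition:

    ems = (2 * sum of kept pair similarities) / (nA + nB)
          * 1 / (1 + (aligned_rmsd / 4)^2)

The score lives in [0, 1]; 1 requires identically sized pockets, perfect
pair similarities, and zero aligned RMSD. The geometric factor halves the
score at 4 Å aligned RMSD. A match is called significant above a plain
threshold (default 0.80).

Residue similarity is a fixed weighted overlap of features (hydropathy,
charge, polarity, aromaticity, side-chain size, conservation) in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import RigidTransform, kabsch_superpose
from .pocketmodel import Pocket, ResidueFeatures

__all__ = [
    "SimilarityMatrix",
    "PocketAlignment",
    "EMSResult",
    "residue_similarity",
    "build_similarity_matrix",
    "optimal_assignment",
    "geometric_prune",
    "ems_score",
    "match_pockets",
]

SIGNIFICANCE_THRESHOLD = 0.80
PRUNE_DISTANCE_CUTOFF = 6.0  # Å
MIN_ALIGNED_PAIRS = 5
RMSD_HALF_SCORE = 4.0  # Å at which the geometric factor reaches 1/2

# Feature weights of the pair-similarity model (sum to 1.0)
W_HYDRO, W_CHARGE, W_POLAR, W_AROM, W_SIZE, W_CONS = 0.30, 0.20, 0.15, 0.10, 0.10, 0.15
HYDRO_SCALE = 18.0  # Gaussian width (squared Å of KD units) of the hydropathy term


@dataclass
class SimilarityMatrix:
    """Residue-pair similarities between two pockets, entries in [0, 1]."""

    values: np.ndarray  # (nA, nB)
    row_ids: list
    col_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("similarity matrix must be 2-D")
        if self.values.size == 0:
            raise ValueError("similarity matrix is empty")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("similarity entries must lie in [0, 1]")


@dataclass
class PocketAlignment:
    """A pruned residue pairing with its rigid superposition."""

    pairs: list[tuple[int, int, float]]  # (index in A, index in B, similarity)
    transform: RigidTransform
    aligned_rmsd: float
    failed: bool = False

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)

    def __post_init__(self) -> None:
        rows = [p[0] for p in self.pairs]
        cols = [p[1] for p in self.pairs]
        if len(rows) != len(set(rows)) or len(cols) != len(set(cols)):
            raise ValueError("alignment pairs must form a partial matching")


@dataclass
class EMSResult:
    ems_score: float
    significant: bool
    alignment: PocketAlignment
    threshold: float = SIGNIFICANCE_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 <= self.ems_score <= 1.0):
            raise ValueError("ems_score must lie in [0, 1]")
        if self.significant and self.ems_score < self.threshold:
            raise ValueError("significant result below its own threshold")


def residue_similarity(fa: ResidueFeatures, fb: ResidueFeatures) -> float:
    """Weighted feature-overlap similarity of two binding residues, in [0, 1]."""
    d_hydro = fa.hydrophobicity - fb.hydrophobicity
    # two empty side chains (glycine pairs) are identical, not dissimilar
    if fa.side_chain_size == fb.side_chain_size == 0:
        size_term = 1.0
    else:
        size_term = min(fa.side_chain_size, fb.side_chain_size) / max(
            fa.side_chain_size, fb.side_chain_size, 1
        )
    s = (
        W_HYDRO * np.exp(-(d_hydro**2) / HYDRO_SCALE)
        + W_CHARGE * (fa.charge_class == fb.charge_class)
        + W_POLAR * (fa.polar == fb.polar)
        + W_AROM * (fa.aromatic == fb.aromatic)
        + W_SIZE * size_term
        + W_CONS * (fa.conservation * fb.conservation)
    )
    return float(min(max(s, 0.0), 1.0))


def build_similarity_matrix(pocket_a: Pocket, pocket_b: Pocket) -> SimilarityMatrix:
    fa = pocket_a.features()
    fb = pocket_b.features()
    values = np.empty((len(fa), len(fb)))
    for i, f1 in enumerate(fa):
        for j, f2 in enumerate(fb):
            values[i, j] = residue_similarity(f1, f2)
    return SimilarityMatrix(
        values=values, row_ids=pocket_a.residue_keys(), col_ids=pocket_b.residue_keys()
    )


def _lsa_max(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return linear_sum_assignment(values, maximize=True)


def optimal_assignment(matrix: SimilarityMatrix | np.ndarray) -> list[tuple[int, int, float]]:
    """Maximum-total-similarity one-to-one matching of size min(nA, nB).

    Solved with the Kuhn-Munkres algorithm. Ties are broken
    deterministically: among all maximum-total matchings, each row in order
    receives the lowest admissible column (lowest row index first, then
    lowest column index). Rectangular matrices are handled by the standard
    zero-padding extension; padded pairs never appear in the output.
    """
    values = matrix.values if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix, float)
    if values.size == 0:
        raise ValueError("empty similarity matrix")
    n_a, n_b = values.shape
    transposed = False
    if n_a > n_b:
        values = values.T
        n_a, n_b = n_b, n_a
        transposed = True

    rows, cols = _lsa_max(values)
    total = values[rows, cols].sum()

    # Canonicalize ties: greedily force each row to its lowest column that
    # still admits an optimal completion. Exact (re-solves the assignment on
    # the reduced matrix); cost is n extra Kuhn-Munkres solves.
    assigned: dict[int, int] = dict(zip(rows, cols))
    forced: dict[int, int] = {}
    free_cols = sorted(set(range(n_b)))
    remaining_rows = list(range(n_a))
    eps = 1e-9 * max(1.0, float(np.abs(values).max()))
    for row in range(n_a):
        candidates = sorted(c for c in free_cols)
        chosen = None
        for col in candidates:
            if values[row, col] + _best_completion(values, row, col, forced) >= total - eps:
                chosen = col
                break
        if chosen is None:  # numerical fallback: keep the solver's column
            chosen = assigned[row]
        forced[row] = chosen
        free_cols.remove(chosen)
        remaining_rows.remove(row)
        total -= values[row, chosen]

    pairs = []
    for row, col in sorted(forced.items()):
        i, j = (col, row) if transposed else (row, col)
        pairs.append((int(i), int(j), float(values[row, col])))
    if transposed:
        pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs


def _best_completion(values: np.ndarray, row: int, col: int, forced: dict[int, int]) -> float:
    """Optimal total over rows > ``row`` with earlier rows fixed and ``col`` used."""
    n_a, n_b = values.shape
    used_cols = set(forced.values()) | {col}
    rest_rows = [r for r in range(row + 1, n_a)]
    rest_cols = [c for c in range(n_b) if c not in used_cols]
    if not rest_rows:
        return 0.0
    sub = values[np.ix_(rest_rows, rest_cols)]
    rr, cc = _lsa_max(sub)
    return float(sub[rr, cc].sum())


def geometric_prune(
    pairs: Sequence[tuple[int, int, float]],
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    distance_cutoff: float = PRUNE_DISTANCE_CUTOFF,
    min_pairs: int = MIN_ALIGNED_PAIRS,
) -> PocketAlignment:
    """Prune an assignment to a geometrically consistent core.

    Iterates: Kabsch on the current pairs, drop the single worst pair whose
    post-fit Cα distance exceeds ``distance_cutoff``, repeat until all pairs
    fit or only ``min_pairs`` remain. If the floor is reached while pairs
    still violate the cutoff, the result is flagged failed (not an
    exception) — the pockets admit no rigid local superposition.
    """
    pairs = list(pairs)
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {len(pairs)}")
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    kept = pairs
    while True:
        a = coords_a[[p[0] for p in kept]]
        b = coords_b[[p[1] for p in kept]]
        sup = kabsch_superpose(a, b)
        moved = sup.transform.apply(a)
        dists = np.sqrt(np.sum((moved - b) ** 2, axis=1))
        worst = int(np.argmax(dists))
        if dists[worst] <= distance_cutoff:
            return PocketAlignment(
                pairs=kept, transform=sup.transform, aligned_rmsd=sup.rmsd
            )
        if len(kept) <= min_pairs:
            return PocketAlignment(
                pairs=kept,
                transform=sup.transform,
                aligned_rmsd=sup.rmsd,
                failed=True,
            )
        kept = [p for k, p in enumerate(kept) if k != worst]


def ems_score(
    alignment: PocketAlignment,
    pocket_a: Pocket,
    pocket_b: Pocket,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> EMSResult:
    """eMS-like pocket similarity from a pruned alignment.

    Normalization uses the mean pocket size (nA + nB)/2, keeping the score
    symmetric; the geometric factor 1/(1 + (rmsd/4)^2) discounts alignments
    with poor local superposition. Failed alignments score 0.
    """
    if alignment.failed:
        return EMSResult(
            ems_score=0.0, significant=False, alignment=alignment, threshold=threshold
        )
    pair_sum = sum(p[2] for p in alignment.pairs)
    coverage = 2.0 * pair_sum / (len(pocket_a) + len(pocket_b))
    geom = 1.0 / (1.0 + (alignment.aligned_rmsd / RMSD_HALF_SCORE) ** 2)
    ems = float(min(max(coverage * geom, 0.0), 1.0))
    return EMSResult(
        ems_score=ems,
        significant=ems >= threshold,
        alignment=alignment,
        threshold=threshold,
    )


def match_pockets(
    pocket_a: Pocket,
    pocket_b: Pocket,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    distance_cutoff: float = PRUNE_DISTANCE_CUTOFF,
    min_pairs: int = MIN_ALIGNED_PAIRS,
) -> EMSResult:
    """Full sequence-order-independent comparison of two pockets.

    Composes similarity matrix -> optimal assignment -> geometric pruning ->
    eMS-like score. Symmetric to within numerical tolerance.
    """
    if not pocket_a.alignable or not pocket_b.alignable:
        raise ValueError("both pockets need >= 5 residues for alignment")
    matrix = build_similarity_matrix(pocket_a, pocket_b)
    pairs = optimal_assignment(matrix)
    alignment = geometric_prune(
        pairs,
        pocket_a.ca_coords(),
        pocket_b.ca_coords(),
        distance_cutoff=distance_cutoff,
        min_pairs=min_pairs,
    )
    return ems_score(alignment, pocket_a, pocket_b, threshold=threshold)
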