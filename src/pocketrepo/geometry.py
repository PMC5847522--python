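"""Rigid-body superposition and structural-similarity metrics.

Implements the geometric primitives the pocket-matching pipeline relies on:
Kabsch least-squares superposition (reflection excluded), paired RMSD,
TM-score and GDT-TS with the standard fragment-seeded iterative search, and
the Matthews correlation coefficient for binding-residue prediction.

TM-score uses d0(L) = 1.24 (L - 15)^(1/3) - 1.8 and normalizes by the
reference (target) length by default; both TM-score and GDT maximize over
superpositions seeded on contiguous fragments and iteratively extended, so
they are invariant under any rigid motion applied to the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch_superpose",
    "rmsd_paired",
    "tm_score",
    "gdt_ts",
    "mcc_sets",
]


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation R, translation t in Å)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1 (no reflections)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_points: int


def _as_points(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must have shape (N, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return x


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing |R m + t - f|."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fc - rot @ mc
    return rot, trans


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Point i of ``moving`` corresponds to point i of ``fixed``. Reflections
    are excluded (proper rotation only). Collinear/degenerate inputs still
    return a valid transform but raise a warning, since the rotation about
    the degenerate axis is then arbitrary.
    """
    moving = _as_points(moving, "moving")
    fixed = _as_points(fixed, "fixed")
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must have identical shapes")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    centered = moving - moving.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        warnings.warn(
            "degenerate (collinear) point set: rotation is not fully determined",
            stacklevel=2,
        )
    rot, trans = _kabsch(moving, fixed)
    transform = RigidTransform(rotation=rot, translation=trans)
    moved = transform.apply(moving)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_points=n)


def rmsd_paired(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """RMSD between paired point sets, optionally after Kabsch superposition."""
    a = _as_points(a, "a")
    b = _as_points(b, "b")
    if a.shape != b.shape:
        raise ValueError("point counts differ")
    if superpose:
        return kabsch_superpose(a, b).rmsd
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# TM-score / GDT: fragment-seeded iterative superposition search


def _check_pairing(
    model: np.ndarray, reference: np.ndarray, pairing: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    if len(pairing) == 0:
        raise ValueError("pairing must be non-empty")
    mi = np.asarray([p[0] for p in pairing], dtype=int)
    ri = np.asarray([p[1] for p in pairing], dtype=int)
    return model[mi], reference[ri]


def _seed_fragments(n_pairs: int, lengths: Sequence[int]) -> list[np.ndarray]:
    seeds = []
    for L in lengths:
        L = max(4, min(int(L), n_pairs))
        starts = range(0, n_pairs - L + 1, max(1, L // 2))
        for s in starts:
            seeds.append(np.arange(s, s + L))
    if not seeds:
        seeds.append(np.arange(n_pairs))
    return seeds


def _iterative_search(
    m: np.ndarray,
    r: np.ndarray,
    score_fn,
    include_fn,
    max_iter: int = 20,
) -> float:
    """Generic fragment-seeded search maximizing score_fn over superpositions.

    ``include_fn(d)`` selects the pair subset refit at the next iteration
    (the d0 inclusion rule for TM-score, the threshold rule for GDT);
    ``score_fn(d)`` evaluates the objective on all paired distances.
    """
    n = len(m)
    best = -np.inf
    if n < 3:
        d = np.sqrt(np.sum((m - r) ** 2, axis=1))
        return float(score_fn(d))
    for seed in _seed_fragments(n, [n, max(n // 2, 4), 4]):
        subset = seed
        prev: Optional[np.ndarray] = None
        for _ in range(max_iter):
            if len(subset) < 3:
                break
            rot, trans = _kabsch(m[subset], r[subset])
            moved = m @ rot.T + trans
            d = np.sqrt(np.sum((moved - r) ** 2, axis=1))
            best = max(best, float(score_fn(d)))
            new_subset = np.flatnonzero(include_fn(d))
            if len(new_subset) < 3:
                break
            if prev is not None and np.array_equal(new_subset, prev):
                break
            prev = subset
            subset = new_subset
    return best


def tm_score(
    model: np.ndarray,
    reference: np.ndarray,
    pairing: Optional[Sequence[tuple[int, int]]] = None,
    norm_length: Optional[int] = None,
) -> float:
    """Template-modeling score of ``model`` against ``reference``.

    ``pairing`` lists (model index, reference index) pairs; identity pairing
    is assumed when omitted and the chains have equal length. ``norm_length``
    defaults to the reference length (normalization by the target).
    """
    model = _as_points(model, "model")
    reference = _as_points(reference, "reference")
    if pairing is None:
        if len(model) != len(reference):
            raise ValueError("identity pairing requires equal lengths")
        pairing = [(i, i) for i in range(len(model))]
    L = int(norm_length) if norm_length is not None else len(reference)
    if L <= 15:
        raise ValueError("norm_length must be >= 16 (d0 positive)")
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    m, r = _check_pairing(model, reference, pairing)

    def score(d: np.ndarray) -> float:
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)

    return _iterative_search(m, r, score, lambda d: d < d0)


GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


def gdt_ts(
    model: np.ndarray,
    reference: np.ndarray,
    pairing: Optional[Sequence[tuple[int, int]]] = None,
) -> float:
    """GDT-TS: mean over {1,2,4,8} Å of the maximal superposable fraction."""
    model = _as_points(model, "model")
    reference = _as_points(reference, "reference")
    if pairing is None:
        if len(model) != len(reference):
            raise ValueError("identity pairing requires equal lengths")
        pairing = [(i, i) for i in range(len(model))]
    m, r = _check_pairing(model, reference, pairing)
    n = len(m)
    fractions = []
    for thr in GDT_THRESHOLDS:
        frac = _iterative_search(
            m,
            r,
            lambda d, t=thr: np.count_nonzero(d <= t) / n,
            lambda d, t=thr: d <= t,
        )
        fractions.append(max(frac, 0.0))
    return float(np.mean(fractions))


def mcc_sets(predicted: set, actual: set, universe: set) -> float:
    """Matthews correlation coefficient of set membership over a universe.

    Returns 0.0 when any confusion-matrix marginal is empty (the coefficient
    is undefined there; zero is the uninformative value).
    """
    predicted, actual, universe = set(predicted), set(actual), set(universe)
    if not predicted <= universe or not actual <= universe:
        raise ValueError("predicted and actual must be subsets of universe")
    tp = len(predicted & actual)
    fp = len(predicted - actual)
    fn = len(actual - predicted)
    tn = len(universe) - tp - fp - fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))
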