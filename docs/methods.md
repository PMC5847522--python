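# Methods

This note documents the models and procedures implemented in `pocketrepo`,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Pocket model

A pocket is a list of binding residues, each carrying its Cα position and a
feature vector: Kyte–Doolittle hydropathy, charge class (−1/0/+1), polarity
and aromaticity flags, side-chain heavy-atom count, and a conservation
weight in [0, 1]. Two constructions are supported:

- **From a holo complex** — residues with any heavy atom within 4.5 Å of any
  ligand heavy atom. The 4.5 Å heavy-atom cutoff is the common contact
  convention; the pocket center is the ligand's heavy-atom geometric center.
- **From a predicted annotation** — the annotated residue list, with the
  centroid of annotated Cα atoms as center unless the annotation carries an
  explicit one. A predicted center counts as *correct* when it lies within
  8 Å (inclusive) of the bound ligand's geometric center.

Conservation defaults to 1.0 (uninformative). Real evolutionary profiles
come from external site-prediction tools; keeping the slot at its neutral
value means the similarity weights need not change when profiles are
supplied. Prediction-confidence percentages map to tiers at ≥ 80% (high) and
≥ 50% (moderate); the boundaries are configurable because the tier names in
the literature come without published thresholds.

For docking-box metadata, the ligand radius of gyration is geometric
(mass-unweighted) and the box edge is 2.9 × Rg floored at 22.5 Å, the
published box-optimization rule for Vina-style search spaces.

## Sequence-order-independent pocket alignment

Residue pair similarity is a fixed weighted overlap:

    s(a, b) = 0.30 exp(−Δhydro²/18) + 0.20·[charge match] + 0.15·[polar match]
            + 0.10·[aromatic match] + 0.10·size_ratio + 0.15·(cons_a · cons_b)

clamped to [0, 1]. `size_ratio` is min/max of the side-chain heavy-atom
counts, defined as 1.0 when both are zero so that a glycine–glycine pair is
a perfect match (the literal min/max ratio would score it 0.9 and break the
self-match identity). The weights are a design choice: hydropathy carries
the most weight, the Gaussian width 18 makes the term drop to ~0.6 at a
hydropathy gap of 3 KD units; a machine-learned pair scorer could replace
this function without touching any other contract (range, symmetry,
ordering).

The optimal one-to-one pairing maximizes total similarity via the
Kuhn–Munkres algorithm (`scipy.optimize.linear_sum_assignment`). Ties are
canonicalized exactly: row by row, each row is forced to the lowest column
that still admits an optimal completion (checked by re-solving the reduced
assignment), so an all-equal matrix yields the diagonal and results are
platform-independent. Rectangular inputs use the standard zero-padding
extension; padded pairs are discarded.

The pairing is then pruned to a geometrically consistent core: Kabsch
superposition on the current pairs, drop the single worst pair whose
post-fit Cα distance exceeds 6 Å, repeat until consistent or only 5 pairs
remain. Reaching the floor while still inconsistent yields a *failed*
alignment (scored 0), not an exception: such pocket pairs admit no rigid
local superposition.

The final similarity is

    eMS = (2 Σ kept pair similarities) / (n_A + n_B) · 1/(1 + (RMSD/4)²)

Mean-size normalization keeps the score symmetric (min- or union-size
normalizations do not). The geometric factor halves the score at 4 Å
aligned RMSD, consistent with meaningful local alignments living in the
2.5–4.5 Å range. Significance is a plain threshold, default 0.80 and
configurable; no null model is fitted.

## Virtual-screening similarity and fusion

Given two rank lists over a common compound library, similarity is
Spearman's ρ computed on the common subset (re-ranked within the subset,
average ranks for ties) — invariant under any strictly monotone transform
of either docking score. At least 3 common compounds are required.

The fusion rule is `combined = (eMS + max(ρ, 0))/2`: the arithmetic mean of
the two evidence channels with negative correlations clamped to zero, since
anti-correlated screens carry no evidence of shared binders. It is the
simplest bounded, monotone choice; it is this package's rule, exposed as a
single function so alternatives can be swapped in.

## BEDROC

Early recognition is scored with the Truchon–Bayly BEDROC. For n actives
among N candidates at ranks r_i (descending score, ties broken by candidate
id for determinism), R_a = n/N:

    RIE    = (Σ e^{−α r_i/N}) / ((n/N)(1 − e^{−α})/(e^{α/N} − 1))
    BEDROC = RIE · R_a sinh(α/2)/(cosh(α/2) − cosh(α/2 − α R_a))
           + 1/(1 − e^{α(1−R_a)})

This closed form is algebraically identical to min/max normalization of the
exponential rank sum (the test suite checks agreement with a direct
implementation to 1e-9), so BEDROC ∈ [0, 1] with 0/1 at the worst/best
possible rankings. α defaults to 20 — the field's convention, putting ~80%
of the weight on the top 8% of the list. The random expectation at α = 20,
R_a = 0.05 is ≈ 0.079 (BEDROC is linear in RIE and E[RIE] = 1 under random
ranking). Box-plot summaries (median, quartiles, 1.5·IQR whiskers) and a
seeded uniform-score baseline support benchmark-style comparisons.

## Statistical potential

A DFIRE-style distance-scaled finite ideal-gas reference potential over
protein–ligand heavy-atom pairs:

    u(i, j, r) = −η ln[ (N_obs(i,j,r) + q) /
                        ((r/r_cut)^α (Δr/Δr_cut) (N_obs(i,j,r_cut bin) + q)) ]

evaluated at bin centers, with α = 1.61, r_cut = 14.5 Å, Δr = 0.5 Å (the
parameters of the original distance-scaled reference-state formulation),
η = 1 and pseudocount q = 1. The r_cut bin anchors the reference, so u there
is 0 by construction; the pseudocount keeps sparse corpora defined; with
q = 0 and counts exactly proportional to the reference, u ≡ 0.

Typing is deliberately coarse and training-data-frugal: protein atoms by
backbone/side-chain role and element (bb.N, bb.C, bb.O, sc.C, sc.N, sc.O,
sc.S, catch-all), ligand atoms by element and aromaticity with halogens
pooled. Energies are in arbitrary units: only signs and orderings are
contract-bearing — absolute magnitudes depend entirely on the training
corpus and are not comparable across corpora.

`compare_source_destination` correlates source-complex energies with the
mean destination energy per drug (Pearson r, regression slope, standard
error of each mean), the quality check used when the same drug is modeled
against both its known and its proposed target.

## Pose construction and transfer

- **Template docking** — the template's bound ligand is carried into the
  target frame by the supplied global transform; the drug's mapped heavy
  atoms (≥ 3 required) are Kabsch-fitted onto the mapped template-ligand
  atoms; unmapped atoms ride the same rigid transform.
- **Transfer** — a significant pocket alignment's rigid transform applied
  to all pose atoms. Exact rigid motion: intra-ligand distances are
  preserved to machine precision.
- **Clash relief** — greedy rigid-body translation descending the penalty
  Σ (2.5 − d)² over protein–ligand pairs closer than 2.5 Å (strict
  inequality at the boundary), 0.1 Å steps along the best of 26 lattice
  directions, total displacement capped at 3 Å. The penalty never
  increases, ligand geometry never changes, and residual clashes are
  reported rather than hidden. This is a deterministic, testable stand-in
  for full all-atom refinement, which is out of scope by design.
- **Consensus** — when one drug reaches one destination through k
  alignments, pairwise heavy-atom RMSDs are computed *without*
  re-superposition (all poses share the destination frame; re-superposing
  would erase the binding-mode differences being measured). The typical
  pose minimizes the mean RMSD to the others; ties go to the lowest index.
  Mean (not median) was chosen as the "RMSD against all other models"
  aggregate.

## Pipeline

The orchestration layer filters drugs (MW 150–550 Da inclusive), targets
(50–999 residues inclusive, model GDT ≥ 0.4 when an estimate is supplied)
and pockets (confidence tier), removes redundancy greedily (fingerprint
Tanimoto > 0.9 for drugs; global-alignment sequence identity over the
shorter chain > 0.80 for proteins; first id becomes the representative),
then runs all-against-all matching, transfer, clash relief and potential
scoring. MW and GDT can be supplied as tabulated metadata — a model's GDT
is not computable from the model alone. A drug–destination pair reachable
via several sources becomes one catalog row carrying every provenance route
and the consensus spread. Every filter decision is logged as a JSON line;
the whole run is a pure function of inputs and configuration, and the
exported TSV/JSON catalogs are byte-identical across re-runs.

## Geometry metrics

Kabsch superposition uses SVD with the determinant correction (reflections
excluded); collinear inputs return a valid transform with a warning. The
TM-score, d0 = 1.24 (L−15)^{1/3} − 1.8 normalized by the reference length,
and GDT-TS (thresholds 1/2/4/8 Å) both maximize over superpositions with
the standard fragment-seeded iterative search: Kabsch fits seeded on
contiguous fragments of length {n, n/2, 4}, extended by the d0 (or
threshold) inclusion rule until stable. Residue pairings are caller-supplied
(identity by default); no sequence alignment is performed. MCC on residue
sets returns 0 when a confusion-matrix marginal is empty.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their parameters including the seed
(numpy PCG64 via `default_rng`, seeded per call, cross-platform stable).

- **Toy pockets** place residues on a jittered 8 Å sphere — the spatial
  scale of a drug-binding site — as Cα+Cβ skeletons with up to two
  side-chain pseudo-atoms: enough geometry for contacts, clashes and
  alignment, with no rotamer chemistry, secondary structure, or realistic
  packing.
- **Derived pockets** keep ⌈overlap·n⌉ of the parent's residues (optionally
  jittered in features and coordinates) and replace the rest with fresh
  random residues: a controllable model of two sites that bind similar
  ligands, and of the misannotation noise that predicted binding sites
  carry.
- **Screening libraries** draw a latent Gaussian affinity per compound for
  each of two pockets with Pearson correlation 2 sin(π ρ_t/6) — the exact
  Gaussian-copula inverse of a target Spearman ρ_t — and subtract an
  enrichment bonus from active compounds' scores. Measured ρ recovers the
  target within ±0.1 at library size ≥ 100 (verified over seeds); zero
  enrichment reproduces the analytic random-BEDROC expectation.
- **The recognition benchmark** gives each query parent 4 actives (overlap
  0.6) and 26 decoys (overlap 0.45), both at feature noise 0.25 and Cα
  noise 0.8 Å, with planted ρ of 0.75 for actives and 0.0 for decoys over
  100-compound libraries. The overlap levels are deliberately close: with
  well-separated overlaps the alignment score alone ranks every active
  first and the benchmark cannot measure what screening fusion adds. This
  regime emulates the hard case — predicted pockets with misannotated
  residues — and on it, fused scoring strictly improves median BEDROC over
  alignment-only scoring, and both beat a shuffled baseline.
- **Potential-training complexes** are a special corpus: sparse Cα-only
  "proteins" (residues > 2·r_cut apart) with ligand-atom anchor distances
  drawn from the r^α reference density itself. This realizes the finite
  ideal-gas reference exactly, so a zero-preference corpus trains to u ≈ 0
  (the null calibration is meaningful, not approximate) and a planted 3–4 Å
  preference for the (bb.C, O.al) pair is cleanly recoverable. A dense
  protein shell cannot serve here: its pair-distance distribution is shaped
  by the shell geometry, not the reference, and every energy would absorb
  that geometric bias.

Passing tests on these fixtures demonstrate the *contracts* — optimality,
symmetry, calibration, orderings, determinism — not performance on real
proteins: none of the generators model real structural variation, chemistry
or docking physics.

## Problem sizes

Default test-suite scales, chosen to exercise every contract at full
strength while keeping the whole suite around a minute: 13–15-residue
pockets; assignment oracle over 1000 random matrices up to 7×7 against
exhaustive enumeration; BEDROC oracle to N = 200 plus 1000-replicate
Monte-Carlo means; recognition benchmark of 20 queries × 30 candidates over
20 seeds; potential recovery on 500 complexes × 20 seeds; pipeline runs
with 2–3 sources and 1 destination.

## Known limitations

- The residue-similarity weights are fixed, not learned; conservation is
  neutral unless profiles are supplied.
- Significance of a pocket match is a plain threshold, not a fitted
  statistical model.
- Clash relief is rigid translation only — no torsional sampling, no
  receptor flexibility, no force field.
- The potential has no solvation or entropy terms and its magnitudes are
  corpus-relative.
- PDB support covers single-model ATOM/HETATM content (first model of
  multi-model files); no mmCIF, protonation, or charge assignment.
- Ligands extracted from PDB hetero groups carry no bond orders; descriptor
  work should start from SDF or SMILES.
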