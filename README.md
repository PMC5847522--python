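# pocketrepo

Structure-based drug repositioning by binding-pocket matching. The package
compares drug-binding pockets between a drug-bound source library and an
unannotated destination library (for example, proteins linked to rare
diseases), transfers drug poses through significant pocket matches, and
scores the resulting complexes — all on either real structures or fully
synthetic fixtures, so every stage is testable without downloads.

It is aimed at computational structural biologists who want a small,
transparent, fully deterministic implementation of the pocket-matching →
screening-corroboration → pose-transfer → statistical-potential pipeline.

## The method

**Pocket matching.** Two pockets are compared sequence-order-independently.
Each residue pair (a, b) gets a similarity in [0, 1] from a weighted feature
overlap (Kyte–Doolittle hydropathy, charge class, polarity, aromaticity,
side-chain size, conservation). The optimal one-to-one residue pairing is
the solution of the assignment problem (Kuhn–Munkres), pruned to a
geometrically consistent core by iterated Kabsch superposition (worst pair
above 6 Å dropped, floor of 5 pairs). The pocket similarity score is

    eMS = (2 Σ kept pair similarities) / (n_A + n_B) · 1 / (1 + (RMSD/4 Å)²)

which is symmetric, lies in [0, 1], equals 1 only for identically sized
pockets with perfect pairs at zero RMSD, and is halved at 4 Å aligned Cα
RMSD. A match is *significant* above a configurable threshold (default 0.80).

**Virtual-screening corroboration.** Pockets that bind similar compounds
rank a screening library similarly; Spearman's ρ between two targets' rank
lists is an orthogonal similarity signal. The fused score is
`(eMS + max(ρ, 0)) / 2`. Early-recognition performance is measured with
BEDROC (Truchon–Bayly, α = 20 by default):

    RIE = (Σ_actives e^{−α r_i/N}) / ((n/N)(1 − e^{−α})/(e^{α/N} − 1))
    BEDROC = RIE · R_a sinh(α/2) / (cosh(α/2) − cosh(α/2 − α R_a)) + 1/(1 − e^{α(1−R_a)})

**Pose transfer and scoring.** Drugs enter source pockets by template-based
docking (least-squares fit through a chemical atom mapping); a significant
pocket alignment carries the pose rigidly into the destination pocket;
steric clashes are relieved by a capped greedy rigid translation; complexes
are scored with a DFIRE-style statistical potential
`u(i,j,r) = −η ln[N_obs(i,j,r) / ((r/r_cut)^α (Δr/Δr_cut) N(i,j,r_cut))]`
(α = 1.61, r_cut = 14.5 Å, 0.5 Å bins) trained on a complex ensemble.
When one drug reaches a destination through several sources, the most
typical pose minimizes the mean heavy-atom RMSD to the other models.

## Worked example

```python
import numpy as np
from pocketrepo import fixtures, pocketalign, vsim

# a pocket and a noisy sibling sharing 80% of its binding residues
parent, structure = fixtures.make_toy_pocket(fixtures.FixtureSpec(seed=11, n_residues=13))
sibling = fixtures.derive_similar_pocket(parent, overlap=0.8,
                                         feature_noise=0.1, coord_noise=0.2, seed=3)

match = pocketalign.match_pockets(parent, sibling)
print(f"eMS = {match.ems_score:.3f}  aligned = {match.alignment.n_aligned} residues "
      f"rmsd = {match.alignment.aligned_rmsd:.2f} Å  significant = {match.significant}")

# screening rank lists for the two pockets with a planted correlation of 0.8
case, ranks_a, ranks_b = fixtures.make_screen_library(200, 10, enrichment=2.0,
                                                      seed=0, rho_target=0.8)
rho = vsim.spearman_rho(ranks_a, ranks_b).rho
print(f"rho = {rho:.3f}  combined = {vsim.combine_scores(match.ems_score, rho):.3f}  "
      f"BEDROC = {vsim.bedroc(case):.3f}")
```

prints

```
eMS = 0.828  aligned = 11 residues rmsd = 0.33 Å  significant = True
rho = 0.788  combined = 0.808  BEDROC = 0.842
```

The sibling pocket keeps 11 of the parent's 13 binding residues with mild
feature and coordinate noise: the geometric pruning retains exactly those 11
pairings at 0.33 Å Cα RMSD, and the two replaced residues plus the noise pull
the eMS score down from 1.0 to 0.83 — just above the 0.80 significance
default. The screening correlation of 0.79 sits near its planted value of
0.8; the fused score (eMS + ρ)/2 = 0.81 combines both lines of evidence. The
BEDROC of 0.84 reflects the planted active enrichment in the library.

A command-line interface mirrors the library
(`pocketrepo match-pockets`, `vs-similarity`, `evaluate-bedroc`,
`train-potential`, `score-complex`, `descriptors`, `similarity`,
`make-fixtures`, ...). Try `pocketrepo --help`.

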