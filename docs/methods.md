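# Methods

## Model overview and assumptions

The package maps allosteric regulation from one holo structure under the
reversed-communication premise: binding at the orthosteric site perturbs
the protein's motion pattern, and pockets whose internal dynamics change
most are candidate allosteric sites. Everything is computed from a
single conformer — no molecular dynamics, no apo crystal structure. The
apo state is the holo structure with the ligand deleted; since the
protein coordinates are shared, every apo/holo difference comes from the
ligand pseudo-node's presence in the elastic network, which is exactly
the perturbation the method is designed to read out.

## Structure handling

PDB input is parsed with gemmi. Only the first model of a multi-model
file is used; alternate locations collapse to the highest-occupancy
conformer (ties broken by altloc letter) so the elastic network sees one
deterministic conformer. Waters are discarded; every other hetero group
is a ligand candidate except single-atom groups (ions), which can still
be selected explicitly but are never auto-chosen. Residues are
identified by author numbering (chain, number, insertion code)
everywhere, including reports. Defaults mirror common server limits:
5 MB input, 6000 residues, both configurable.

Redundant-chain removal groups chains at ≥ 95% global sequence identity
(Biopython pairwise alignment, identity = matched columns / alignment
length — the standard crystallographic-copy cutoff) and keeps, per
group, the chain contacting a ligand, then the longest, then the first
identifier. The operation is idempotent.

## Pocket detection

Alpha-sphere detection on heavy atoms: Delaunay tetrahedra whose
circumsphere radius lies in [probe_min, probe_max] = [3, 6] Å contribute
their circumcenters as probe spheres. Because Delaunay circumspheres are
empty, probes never clash with atoms, and the construction commutes with
rigid motions — a property the test suite checks directly, and the
reason this scheme was chosen over a grid scan, which breaks rotational
invariance. Probes cluster by single linkage at 4.5 Å; a residue lines a
pocket when a heavy atom is within 5 Å of a probe; clusters lining fewer
than 4 residues are discarded as noise. Pockets are ordered by
descending probe count (a volume proxy), ties by lining identity, so
output order is deterministic. Pockets whose probes come within 4.5 Å of
the orthosteric ligand are flagged and excluded from classification but
retained in reports.

Caveat: near-degenerate point sets (exact lattices) can flip Delaunay
simplices under rotation in floating point; the synthetic fixtures
jitter radial positions so the triangulation is generic.

## Elastic network and correlations

Isotropic Kirchhoff (GNM-style) model on residue representative
coordinates (Cα when present), cutoff 10 Å, uniform spring constant 1
(correlations are invariant to it). The covariance is the Moore-Penrose
inverse of the Laplacian computed by eigendecomposition with exactly one
zero mode per connected component removed — not an rcond threshold — so
it matches a dense `pinv` oracle to 1e−8. An anisotropic (ANM)
formulation sits behind a flag (3N×3N Hessian, six rigid modes, 3×3
blocks traced to scalars); the isotropic form is the default because a
scalar per pair is what "mean motion correlation" consumes downstream.

The ligand enters the holo network as one pseudo-node at its heavy-atom
centroid with the same spring constant — the simplest perturbation
consistent with a single bound group. A ligand beyond the cutoff of
every residue is tolerated as an explicit null perturbation: its
covariance row is zero, its correlations are reported as zero, and every
pocket RAE is exactly zero — a limit the acceptance tests pin down. Any
other disconnection is an error naming the component sizes.

## RAE

Interaction strength between lining residues is |C_ij|; the per-residue
RAE is the L1 change of its in-pocket interactions between apo and holo,
and the pocket RAE is the sum over lining residues. The interaction
measure is deliberately isolated behind `interaction_matrix` so that a
contact-energy or covariance-based measure can be swapped in without
touching the RAE algebra. Correlation magnitude was chosen because it is
the only pairwise dynamic quantity already defined in the workflow,
keeps the RAE purely dynamics-driven, and responds directly to ligand
addition. No cross-pocket or cross-protein normalization is applied; the
classifier's z-scoring absorbs scale.

## Site classifier

Discrete AdaBoost over depth-1 threshold stumps, 100 rounds by default.
The stump search is exhaustive over features × midpoints × polarity with
deterministic tie-breaks; rounds stop early at zero error (the stump
gets the eps-capped vote weight) or when no stump beats chance.
Allosteric sites are rare among surface pockets (≈ 9% in curated
benchmarks), so initial weights equalize the class masses
(positive-class factor n_neg/n_pos); plain AdaBoost degenerates under
that imbalance. Features are z-scored with parameters stored in the
model, making predictions invariant to affine feature shifts. Confidence
is the logistic of the normalized margin Σα_t h_t / Σα_t, so zero margin
is exactly 0.5 and the positive call is confidence ≥ 0.5.

No curated allosteric-site corpus ships with the package: production
models train on any user-provided labeled table (TSV: protein_id,
pocket_id, hydrophobicity, flexibility, rae, label). `evaluate` computes
the three benchmark metrics — site-level recall, per-protein recall, ROC
AUC — on any such table. sklearn's AdaBoost implementation is used only
as an independent cross-check in the tests, never as the implementation.

## Pathways and coupling

Edges exist only between ENM contact pairs (pathways traverse physically
contacting residues) with weight 1/max(|C_ij|, 1e−6); the absolute value
keeps weights positive — anticorrelated motion is still strong coupling
— and the floor keeps them finite. Shortest routes are Dijkstra
(networkx); among equal-cost routes the lexicographically smallest
residue sequence is returned, so reports are reproducible. Pathway
residue sets include the sink and intermediates and exclude the ligand
anchor; coupling (A, B) is the shared fraction of A's pathway, giving a
unit diagonal, [0, 1] range, coupling 1 whenever A's pathway nests in
B's, and asymmetry whenever lengths differ.

## Synthetic data: what it emulates and what it does not

The shell fixture (60 pseudo-residues jittered around a 6 Å cavity with
a 55° aperture, CA+CB pseudo-atoms, standard residue names cycling
ALA/ILE/ARG) emulates a concave surface pocket with known lining,
plus three ligand placements: in the cavity (orthosteric), on the outer
wall (bound but distal to the cavity), and beyond network reach (null
perturbation). The feature-table generator plants two Gaussian classes
with a +3 sd shift on the pocket-RAE feature at 9% positives, grouped
into pseudo-proteins of ten pockets. `shell_feature_table` labels real
detected pockets by planted-cavity coverage, producing a classifier that
operates on genuine pipeline feature scales.

These fixtures do not emulate real side-chain packing, B-factor
gradients, sequence-dependent flexibility, multi-domain architecture, or
the label noise of curated allosteric annotations. Passing tests
therefore demonstrate the algorithms' correctness and internal
consistency, not benchmark-level accuracy on real proteins; published
benchmark figures require the external curated corpus and are out of
scope here.

## Numerical choices and degenerate inputs

- Zero-mode removal by exact count per component; a nonzero "zero"
  eigenvalue above 1e−6 of the spectral scale raises a degeneracy error.
- Correlations are symmetrized and clipped to [−1, 1] against round-off;
  diagonals set to exactly 1.
- Structures with fewer than 5 heavy atoms, or collinear/coplanar
  geometry, yield an empty pocket list rather than an error.
- Tie-breaks are total and documented everywhere randomness could creep
  in: stump selection by (error, feature, threshold, polarity), top-RAE
  by residue ordering, pocket order by (−size, lining), path choice
  lexicographic.
- Problem sizes in the test and acceptance suites (shell of 60 residues,
  graphs of 8–12 nodes, tables of 500 rows, 20–100 seeds) were chosen as
  the smallest sizes at which each property is non-trivial; all scale
  linearly upward.

## Known limitations

- Pocket inventories will not match any specific external cavity
  program; parameters are tuned for the alpha-sphere scheme above.
- The RAE interaction measure is dynamics-only; energetic interaction
  changes (e.g. contact potentials) are plausible alternatives behind
  the same interface.
- Correlations derive from the holo network topology alone; an option to
  average apo and holo dynamics exists in concept but pathways currently
  use the holo state, the state the user uploads.
- Confidence is a calibrated-looking but uncalibrated logistic margin;
  compare confidences within one run rather than across proteins.
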