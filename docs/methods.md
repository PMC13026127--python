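# Methods

## Model

`rotalib` estimates the conditional probability P(r | x) of sidechain
rotamer r given a discretized context vector x, independently for each
amino acid. The pipeline is: define rotamers by clustering observed
conformations; accumulate raw counts C_r(x) on the context grid; smooth
them with a separable circular Gaussian kernel; convert to probabilities
with a Dirichlet posterior; predict by maximum posterior.

**Assumptions.** Rotamer preferences vary smoothly over backbone dihedral
space (justifying local kernel smoothing); rotamers are discrete,
geometrically coherent basins representable by a single canonical χ vector;
context axes are conditionally sufficient — anything not on the grid
(solvent, electrostatics, crystal contacts) is noise from the model's point
of view.

## Rotamer clustering

Conformations are compared as reconstructed 3-D sidechains in a **shared
canonical backbone frame** (N, CA, C at fixed ideal positions), so RMSD
depends on χ only and needs no superposition. Reconstruction uses a fixed
internal-coordinate table (Engh–Huber-like bond lengths/angles) and NeRF
placement; the chi-bearing atom of each χ quadruple is placed with exactly
that quadruple as reference, so measurement round-trips reconstruction to
< 1e-6°. Symmetric atom names (PHE CD1/CD2 …) are **not** permuted during
RMSD — clustering stays purely geometric and deterministic; two-fold
symmetry is handled at evaluation time instead. PRO is reconstructed
open-ring (approximate closure); only relative RMSD matters.

The three phases:

1. *Sequential initialization* — in a seeded random order, each
   conformation joins the first cluster whose centroid is within t, with
   the centroid recomputed after every addition, else it seeds a new
   cluster.
2. *Refinement* — repeated passes move a conformation to the nearest
   centroid when strictly closer and within t, recomputing both affected
   centroids immediately; converges when a pass makes no move
   (`max_refine_iters` = 100 guards against oscillation and logs if hit).
3. *Merging* — the closest centroid pair below 0.7 t is merged repeatedly
   (deterministic closest-first scheduling) until none qualifies.

A centroid is the conformation reconstructed from the per-dimension
circular mean of member χ — always a valid sidechain geometry, unlike a
coordinate-space mean. Equidistant ties in phases 1–2 go to the lowest
cluster index (seed-independent). Rotamer ids are assigned by descending
member count, ties by ascending canonical χ1; this ordering is an artifact
convention, and it makes the argmax tie-break (lowest id) favor the
population mode.

Per-amino-acid thresholds t range from 0.30 Å (rigid aromatics, short
sidechains) to 0.90 Å (GLU) — see `clustering.DEFAULT_THRESHOLDS`. They are
interpreted against this package's ideal-geometry table; a different
geometry table would rescale all RMSDs uniformly.

## Context grid

Periodic axes cover (−180°, 180°] in uniform bins, default width 10°
(36 bins), half-open [lo, lo + w) with +180° wrapping onto the first bin.
Categorical axes hold ordered labels. The default third axis is the
biochemical class of the **nearest non-sequential contact**: among residues
other than the query and its i±1 chain neighbours, the one with the
smallest heavy-atom distance to the query's sidechain; if that distance is
≤ 5.5 Å (closed ball) the contact's class is used, else the reserved class
`none` — the extra class keeps every residue predictable. The hydrophobic
set is {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS}; everything else
(including GLY) is non-hydrophobic. The exclusion window (i±1), the
distance definition (sidechain-to-any vs Cβ–Cβ) and the class map are all
configurable; the defaults above are recorded in library metadata.

A **global bin support** — the set of bins observed anywhere in the
training corpus — optionally restricts the prediction domain: queries off
the support return `out_of_grid` and are excluded (symmetrically for all
compared methods) from accuracy denominators. Tensors are stored densely;
the support restricts prediction, not storage.

## Smoothing and posterior

The 1-D kernel is w_j ∝ exp(−j²/2σ²), j ∈ [−R, R], **normalized to sum 1
per axis**. Normalization is a deliberate choice: it makes smoothing
mass-conserving on periodic grids and keeps α interpretable as a total
pseudo-count regardless of kernel size. Periodic axes are convolved with
wrap-around; categorical axes use the truncated kernel renormalized at the
boundary (each output bin's effective weights still sum to 1, so no mass
leaks off the axis ends, though truncated axes are not exactly
mass-conserving bin-by-bin).

The posterior is P(r|x) = (C̃_r(x) + α π_r) / (Σ_r′ C̃_r′(x) + α) with
uniform π by default. Limits worth knowing: an empty bin returns exactly
π; α → 0 with radius 0 on an occupied grid returns raw relative
frequencies (the classical frequency-library special case); radius 0 is an
identity smoothing. An optional *fill-missing-only* mode (off by default)
uses raw counts wherever a bin is occupied and smoothed counts only in
empty bins.

**Defaults**: α = 40, R = 1 bin, σ = 1.0 bin on every axis — modest
regularization that does not blur distinct conformational basins. On
well-sampled data the prediction is insensitive to α across 20–100 (the
posterior argmax is count-dominated); σ and R matter only marginally. The
`sweep` command reproduces this analysis on any corpus.

## Baseline

The comparison baseline reduces each χ to three canonical states
(g+ = [0°, 120°), t = [120°, 180°] ∪ (−180°, −120°), g− = [−120°, 0°)),
bins residues on the same 10° φ/ψ grid without interpolation, and predicts
the circular-mean χ of the most frequent state tuple (ties by lexicographic
state order g+ < t < g−). Terminal non-rotameric χ (ASN/ASP/GLN/GLU
carboxamide/carboxylate angles) are binned with the same 3-state rule — a
documented simplification of published non-rotameric handling. With
rotamers fixed to the canonical state centers, no smoothing and a vanishing
prior, the Dirichlet model's argmax coincides with this baseline in every
occupied bin (tested).

## Evaluation

Δχ = min(|χ_pred − χ_true|, 360° − |χ_pred − χ_true|) ∈ [0°, 180°];
two-fold symmetric pairs (ASP χ2, PHE χ2, TYR χ2, VAL χ1 — the set is
configurable) are folded to [0°, 90°] via min(Δχ, 180° − Δχ). VAL χ1 is
kept in the default symmetric set for convention-compatibility despite its
chemistry. A χ_k counts as correct only when χ1…χk are all ≤ 40°
(inclusive boundary). MADχ pools all symmetry-corrected per-χ deviations
over residues and positions; a per-residue-mean variant exists
(`mad_chi(..., per_residue_mean=True)`) and is the unit used for paired
testing, where each residue contributes one mean-deviation difference.
Out-of-grid residues of either method are excluded from both methods'
numerators and denominators.

Statistics: paired two-tailed t (closed form, verified against scipy to
1e-9), Cohen's d = mean/sd of differences, seeded percentile bootstrap
(default 1000 resamples; note percentile intervals undercover slightly
below n ≈ 50), McNemar on the 2×2 correctness table
((b−c)²/(b+c), continuity correction off by default, p from χ²₁;
b + c = 0 reports p = 1), and Bonferroni α/n for per-amino-acid families.
A zero-variance difference vector with zero mean reports t = 0, p = 1 by
convention.

## Synthetic test bed

The generators define the conditions everything is tested under:

- `make_field` — a smooth ground truth P*(r | φ, ψ): per-rotamer weight
  surfaces built from periodic Gaussian bumps over the torus, normalized
  pointwise; rotamer χ1 means spaced ≥ 60° apart. Default angular noise
  σ = 8° (wrapped normal ≈ von Mises at these widths).
- `sample_residues` — φ/ψ uniform on the torus (so every bin is
  exercised; a Ramachandran-biased option would be more realistic but is
  not the default), rotamer drawn from the local weights, χ = mean +
  wrapped noise, coordinates reconstructed so structure-level paths run.
- `planted_clusters` — k χ-space centers whose reconstructed centroids are
  verified (not assumed) to be ≥ separation·t apart, plus wrapped-Gaussian
  members.
- `planted_contact_structure` — a toy 4-residue arrangement plus one
  spatial neighbour at an exact (±0.01 Å, verified) minimal heavy-atom
  distance.
- `build_chain_records` — a real NeRF-continued polypeptide whose parsed
  φ/ψ/χ round-trip the requested values; written to PDB (0.001 Å
  quantization → ~0.1° torsion error) or full-precision mmCIF (< 1e-6°).

What passing these tests does **not** show: performance on real
crystallographic data. The synthetic fields have uniform backbone coverage,
exactly Gaussian noise, no correlation between χ dimensions beyond the
rotamer identity, no experimental error, no crystal contacts and no
sequence context. Absolute accuracies on synthetic corpora are properties
of the chosen field, not of proteins.

## Numerical choices and degenerate inputs

- Angles wrapped to (−180°, 180°]; bins half-open; +180° ≡ −180°.
- Circular mean is undefined (error) when the resultant length is < 1e-12.
- Dihedrals require non-collinear points (error otherwise); they are
  rotation/translation-invariant to < 1e-9°.
- Posterior normalization holds to 1e-9 per bin; periodic smoothing
  conserves per-rotamer mass to 1e-9.
- α = 0 demands a fully occupied grid (error otherwise).
- Argmax ties at prediction go to the lowest rotamer id; baseline ties to
  lexicographic state order.
- The RDL v1 text format stores counts with full float repr (bit-exact
  round-trip) and posteriors with 10 significant digits; a written file
  re-read and re-written is byte-identical.

## Problem sizes

Default test/verification sizes were chosen to make the statistical
properties decisive at desk scale: 50 000 training residues for parameter
recovery (~38 raw counts per 10° bin), 10 000 test residues for accuracy
comparisons, 60–180 conformations per planted clustering fixture, 500
trials × 1000 resamples for bootstrap coverage.

## Known limitations

- No adaptive/von-Mises KDE bandwidths; smoothing is fixed-bandwidth by
  design, with sparsity handled by the prior.
- Hierarchical conditioning (χ2 given predicted χ1) is expressible as an
  extra grid axis but no convenience wiring is provided.
- The contact descriptor is binary (plus `none`); richer descriptors
  (solvent accessibility, contact density) are out of scope.
- Ring closure for PRO (and exact ring geometry for HIS/TRP) is
  approximate; this biases absolute RMSDs slightly but uniformly.
- Baseline non-rotameric χ handling is the simplified 3-state rule above.
- No occupancy/B-factor/resolution filtering during parsing; first model
  only, altloc 'A' or blank only, hydrogens ignored.
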