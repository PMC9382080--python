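# Methods

This note records the models and procedures `ambiclass` implements, the
defaults it ships, and the design decisions taken where the problem
leaves genuine freedom.

## Residue classes and labeling

The package distinguishes three conformational classes of protein
residues:

- **order** — residues that are rigid across experimentally solved
  conformers (conformer clusters whose maximum pairwise RMSD stays
  within 2 Å), or that keep the same regular secondary structure in both
  members of a fold-switch structure pair (raw labels O and S);
- **ambiguous** — residues that undergo a conformational rearrangement:
  disordered regions that fold upon binding (T) or residues that change
  secondary-structure state between two conformers of the same sequence
  (C);
- **disorder** — residues in disordered flanking regions with no
  annotated ordering transition (D).

Fold-switch labeling compares two per-residue secondary-structure
annotations of an *identical* sequence.  Annotations arrive in the
8-state DSSP alphabet and are simplified first; the default mapping is
strict — only H is helix and only E is strand, everything else (G, I, B,
T, S, `-`) is coil.  An `extended` dialect (G, I → helix, B → strand) is
available because both groupings are common downstream of DSSP, but the
strict reading is the default and is what the tests pin.  Comparison
happens at 3-state granularity, so an α-helix ↔ 3₁₀-helix change is not
a switch.  Positions that stay helix or stay strand are S; coil–coil
positions are excluded (they are likely disorder, and keeping them would
contaminate both classes); *every* other combination, including
transitions to or from coil, is C.  This makes S + C + excluded a
partition of the sequence, which the property tests enforce.

The raw→merged mapping (O, S → order; T, C → ambiguous; D → disorder;
excluded → none) is total and count-preserving.

### Rigidity check

Conformer-set rigidity is the maximum over all unordered conformer pairs
of the minimal least-squares superposition RMSD, compared inclusively
against a 2.0 Å threshold.  Superposition centers both point sets and
finds the optimal proper rotation (Kabsch procedure, via
`scipy.spatial.transform.Rotation.align_vectors`, which restricts to the
det = +1 branch).  Only Cα atoms are used — the standard atom selection
for backbone conformational-diversity thresholds — and residue
correspondence is by sequence position; sets with different atom counts
are rejected rather than aligned.  Collinear point sets have a
non-unique optimal rotation but a well-defined minimal RMSD; the
implementation suppresses the degeneracy warning and returns that value.
The unit and acceptance tests cross-check the closed form against an
independent numerical rotation search (random rotation grid plus
Nelder–Mead refinement) to 10⁻³ Å.

## The seven-feature vector

Each residue carries seven sequence-predicted, unitless scores: backbone
dynamics, side-chain dynamics, helix/sheet/coil conformational
propensity, early folding propensity, and disorder.  Scores are
validated for finiteness only, except disorder which must lie in [0, 1];
the other predictors' ranges are tool-dependent (typically within
[0, 1.2]) and are not clamped.  Residues with any missing component are
dropped and logged, never imputed — no defensible imputation rule exists
for these scores.  Sequences shorter than 20 residues are rejected,
the minimum the upstream predictor suite accepts.

Feature providers implement a one-method contract
(`predict(protein_id, sequence) -> table`).  The file-backed provider
replays precomputed TSVs; the synthetic provider draws seeded uniform
scores for plumbing tests; an adapter class exists for the external
b2bTools predictor suite but is optional — the package builds and tests
without it, and nothing else depends on it.

Backbone scores are banded as flexible (< 0.69), context-dependent
(0.69–0.80, closed on both ends) and rigid (> 0.80).  The closed
interval follows from reading "between 0.69 and 0.80" inclusively
against a strictly-below-0.69 flexible region.

## Forest models

Three presets mirror the three dataset styles:

| preset           | classes                     | forest                                    | split |
|------------------|-----------------------------|-------------------------------------------|-------|
| `disprot_codnas` | O / T / D                   | 75 trees, depth 15, split 5, leaf 1, no bootstrap | 90/10 |
| `foldswitch`     | S / C                       | same as above                              | 90/10 |
| `combined`       | order / ambiguous / disorder | 25 trees, depth 15, split 5, leaf 5, bootstrap | 70/30 |

The published best hyperparameters are the defaults; grid search over
`n_estimators {25,50,75,100} × max_depth {5,10,15,None} ×
min_samples_split {2,5,10} × min_samples_leaf {1,5} × bootstrap
{True,False}` by 3-fold CV macro-F1 is available but off by default.
Splits are stratified by class (the source material is silent on this;
stratification makes results reproducible under the severe class
imbalance) with test size `round(n × fraction)`.  No class weighting or
resampling is applied.  All stochastic stages consume an explicit seed
(default 42).  Metrics are reported at full precision and additionally
half-up-rounded to 2 decimals for report tables.  Classes with zero
predicted positives report precision 0 with a warning rather than NaN.

## Rule surrogate

The interpretability route is a surrogate: an ordered rule list fitted
to the *forest's predictions*, so its fidelity (fraction of agreement
with the forest) measures how much of the forest it explains.

The learner is a native sequential-covering implementation in the RIPPER
family rather than a binding to an external rule-learning tool, so the
pipeline is self-contained.  Classes are processed from least to most
frequent (ties broken lexicographically); the most frequent class is the
default.  Per rule, the remaining examples are split 2/3 grow – 1/3
prune (stratified); conditions `feature ≤ t` / `feature ≥ t` with t
restricted to midpoints between adjacent observed values are added
greedily by FOIL information gain until no negatives remain or no
condition has positive gain; the rule is then pruned back on the prune
split under the (p−n)/(p+n) metric.  Induction for a class stops when a
candidate rule's prune-split error exceeds the error tolerance (default
0.5, the better-than-chance cutoff) or its coverage falls below the
minimum (default 2).  Covered examples are removed after each accepted
rule.  The MDL-based stopping criterion and optimization passes of the
original algorithm are deliberately replaced by the explicit tolerance —
a documented simplification; bit-exact equivalence with external rule
learners is not claimed.  Under a fixed seed the learner is fully
deterministic, and the rule count is monotone in the tolerance.

## Context analyses

**PTM consolidation.**  Evidence databases are unioned per (protein,
position, type); types with fewer than two databases of evidence are
dropped; if more than one type survives at a position the site is
reported once as "multiple".  The ≥2-evidence filter is applied *before*
the multiple-typing, so a single-evidence type can never contribute to
"multiple".  Sites beyond the supplied sequence length are dropped and
logged.  Counts downstream are site-level.

**Enrichment.**  All enrichment fractions are `count / (residues
assigned to the class)`, with the denominators recorded in the output;
raw counts are always emitted alongside.  In origin mode the somatic
column is additionally divided by the global somatic/germline count
ratio, making the two columns directly comparable; the factor is
recorded in the table's metadata.  Mutation sets are first filtered to
proteins carrying at least one deleterious and one benign record.

**pLDDT stratification.**  Joined (pLDDT, feature, secondary-structure)
rows are binned into per-SS 2D grids, default bin widths 2.5 pLDDT units
× 0.02 score units (configurable; the defaults resolve the 0.69/0.80
band structure without sparse cells at desk-scale n).  Rows with pLDDT
outside [0, 100] are rejected and logged; grid totals partition the
accepted rows.

## Synthetic data

The generator produces every pipeline input with controlled structure;
its defaults are the package's study conditions.

- **Class priors** default to 0.512 / 0.350 / 0.138
  (order/ambiguous/disorder), the composition of the merged benchmark
  residue pool.
- **Class-conditional features** are truncated normals ([0, 1.2], or
  [0, 1] for disorder).  Defaults place the classes in the qualitative
  bands of the backbone-dynamics convention — order backbone 0.85 ± 0.05
  and disorder score 0.05; ambiguous 0.76 ± 0.06 and 0.45; disorder
  0.65 ± 0.06 and 0.85 — with the remaining features given plausible,
  weaker separations.  These are invented, fully configurable plumbing,
  never presented as measured values.
- **Planted-rule data** draw features uniformly on a 0.01 grid so a
  planted threshold always lies on a grid point; a midpoint learner can
  therefore recover it to within half a grid step, which is why the
  recovery tests use a ±0.02 tolerance.
- **Structure pairs** draw helix/strand/coil segments (lengths 3–12) and
  switch each non-coil position independently with the requested
  probability.
- **Conformers** are rigid motions of a 3.8 Å-step random-walk Cα chain
  plus isotropic Gaussian noise; with zero noise all conformers are
  congruent.
- **Context tables** couple pLDDT linearly to the backbone score
  (`clip(−122.5 + 250·backbone + N(0, 8²), 0, 100)`, mapping backbone
  0.85 → ≈ 90 and 0.65 → ≈ 40) and draw PTM/mutation records per residue
  at per-class rates (each planted PTM site is emitted from 2–3 evidence
  databases so consolidation keeps it; deleterious mutations are mostly
  somatic, benign mostly germline).
- One global seed fans out to fixed per-table child seeds.

What the generator does *not* emulate: realistic 3D geometry, realistic
amino-acid composition differences between classes, sequence–feature
coupling along the chain (features are iid given the class), and the
error modes of real feature predictors.  Passing recovery tests
therefore show that the pipeline's machinery is correct and
well-calibrated under its stated assumptions — not that the published
real-data scores are reproduced; those depend on curated external
datasets that are out of desk-scale reach.

## Problem sizes and numerical choices

The test and acceptance workloads use n = 2,000 residues for
planted-rule recovery (5 seeds), n = 3,000 for three-class forest
recovery (5 seeds, 70/30 split), 20 random 5-point instances for the
RMSD cross-check, and 15–60 proteins for the end-to-end fixtures —
sizes at which the recovery margins are already wide (macro-F1 ≈ 0.99
against a 0.9 bound) while the whole suite runs in seconds.
Ties: report rounding is half-up (0.625 → 0.63); rule-class ordering
ties break lexicographically; threshold candidates are midpoints, so
learned thresholds never coincide with observed values.  Degenerate
inputs (empty tables, single classes, single conformers, zero class
totals) are either well-defined (single conformer → rigid at 0.0 Å) or
rejected with explicit errors, as listed in the API docstrings.

## Known limitations

- The published real-data performance tables are used only as
  arithmetic consistency references; retraining on the real DisProt /
  CoDNaS / fold-switch residue sets requires external downloads and is
  out of scope.
- The rule learner omits RIPPER's global optimization passes; rule lists
  may be slightly longer than an optimized learner would produce.
- No sequence alignment between non-identical conformer sequences, no
  insertion codes, no isoform mapping for PTM/mutation positions.
- The command-line `featurize` ships with the synthetic provider; real
  feature prediction requires the optional external predictor suite.
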