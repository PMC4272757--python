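# Methods

This note documents the models, conventions and numerical choices behind
`mmpamp`, and what its synthetic-data tests do and do not establish about
real datasets.

## Matched pairs and transformations

A molecule is standardized to a canonical SMILES; uniqueness is tracked by
the InChI key of that structure (stereochemistry retained by default, a
flag discards it). Salts and mixtures are rejected rather than stripped:
the pair semantics below assume a single covalent species, and silently
keeping the "parent" component would make pair deltas depend on an
undocumented convention.

**Fragmentation.** Breakable bonds are the acyclic single bonds between
two heavy atoms; rings and multiple bonds are never cut. Cutting k such
bonds (k = 1–3) splits the molecule into k + 1 components. A valid
scaffold/variable split takes as the *variable part* the single connected
component that touches all k cuts (for k = 1, the smaller component); the
*scaffold* is everything else and is written, for k ≥ 2, as a
dot-separated multi-component fragment. The variable part must have at
most `max_variable_atoms` (default 10) heavy atoms and strictly fewer than
the scaffold. Molecules with more than 40 breakable bonds are skipped to
bound the combinatorial cost. Additionally, every symmetry-distinct
hydrogen position yields a single-cut record with an explicit-hydrogen
variable part (atom count 0), which is what makes hydrogen→group
replacements (H→Cl, H→COOH) first-class transformations.

**Canonical fragment keys.** Fragments are written as SMILES with
atom-map-labelled wildcards `[*:1]..[*:3]`. Within a fragmentation record,
labels are assigned from the canonical atom ranking of the scaffold and
inherited by the variable part through the cut-bond pairing, so the same
chemical split always produces byte-identical keys regardless of input
atom order. For transformation identity, the two variable fragments of a
pair are relabelled *jointly* (the same permutation on both sides, since
the labels name shared scaffold positions) to the lexicographically
smallest pair of canonical SMILES, then oriented so `left ≤ right`. A pair
whose own direction runs right→left carries sign −1 into the statistics.

**Pairs and the index.** The index maps scaffold key → (molecule,
variable fragment). Two molecules sharing a scaffold entry with distinct
variable fragments form a matched pair, subject to a whole-molecule ECFP4
(Morgan radius 2, 2,048 bits) Tanimoto filter, default 0.50. One molecule
pair can match on several (nested) scaffolds; each match is recorded, but
all records of the same unordered molecule pair share a pair-group id and
each transformation counts a molecule pair at most once — the double
counting that would otherwise inflate N is the artifact to avoid.

## Significance testing

For a continuous endpoint, the N usable pairs of a transformation are
split into `n_pos` (delta > tie tolerance, default 1e−9), `n_neg`
(delta < −tolerance) and ties, which are excluded; the p-value is the
exact binomial lower tail `P[Bin(n_pos+n_neg, 0.5) ≤ min(n_pos, n_neg)]`,
computed by big-integer summation (no approximation; values below the
smallest positive float are clamped to it so the log-scale significance
level stays finite). For a binary endpoint the before-composition sets the
null rate and the p-value is the smaller lower tail at the after-counts;
with a degenerate before-rate (all active or all inactive) the point-mass
distribution applies, so e.g. full deactivation of an all-active set has
p = 0 by the formula — a documented asymmetry of taking lower tails on
both terms.

Transformations with fewer than `min_pairs` (default 5) usable pairs are
reported but untested; 5 is the smallest N at which the sign test can
reach 0.05 (0.5⁵ ≈ 0.031). Holm–Bonferroni runs per endpoint across all
tested transformations — once on the combined evidence (the headline
decision) and once on the experimental-only subsets (used for provenance
classes). Holm is implemented directly (it is four lines) and is
cross-checked against `statsmodels.multipletests(method="holm")` in the
test suite.

**Pair values and provenance.** Per side, an experimental value always
wins; a predicted value fills gaps unless it is flagged out of the model's
applicability domain (configurable). A pair is *experimental* only when
both sides are experimental; mixed pairs count as predicted evidence
(conservative attribution). Experimental-only statistics are computed on
the experimental subset in isolation, so adding predictions can never
change them.

**Applicability-domain bootstrap.** When predicted pairs contribute,
`n_replicas` (default 1,000) replicas perturb each predicted value
independently — Gaussian noise with σ equal to the stated prediction
uncertainty for continuous values, label flips with the stated
misclassification probability for binary ones; experimental values are
never perturbed. Each replica's counts and p-value are recomputed and the
**median** replica p-value is compared to α: robust, monotone in the noise
level, and equal to the unperturbed p-value when all uncertainties are
zero. Perturbation is applied per pair side; a molecule appearing in
several pairs of one transformation is perturbed independently in each,
a simplification that slightly *understates* the replica correlation a
shared molecule would induce. Replica draws are seeded per transformation
from (run seed, CRC32 of the transformation id), so results do not depend
on iteration order and are bit-for-bit reproducible.

**Provenance classes.** `experimental` — significant on experimental
pairs alone; `amplified` — not significant (or untestable, e.g. 4 pairs)
alone, ≥ 1 experimental pair, significant on combined evidence;
`predicted` — significant with no experimental pairs; `none` otherwise.

## Optimization

Only Holm-significant transformations whose effect matches the requested
direction and clears the practical threshold (default 1.0 log unit for
continuous endpoints; 0.55 deactivation ratio for binary) are applied.
Application reuses the fragmenter: every scaffold/variable split of the
target whose variable part equals the source fragment (up to attachment
relabelling — all matching permutations are enumerated) is an application
site; the target fragment is attached with the corresponding label
pairing, products are standardized, deduplicated on the InChI key, and
invalid-valence or failed reassemblies discarded. Matching is purely
topological: no synthetic feasibility or stability filtering is applied,
and chemical context (electronic environment of the site) is ignored.
Products are filtered by Tanimoto similarity to the original (default
0.50) and scored with the supplied predictor; a hit is any kept product
whose prediction moves the right way, and effectiveness is hits/kept
(undefined when nothing is kept). Per-transformation breakdowns are
available because a genuinely useful replacement can be diluted, in the
totals, by co-selected transformations whose products are neutral.

## The synthetic library

`generate_library` decorates built-in drug-like scaffold cores (14–20
heavy atoms, one marked substitution site) with a vocabulary of small
substituents (default: H, methyl, hydroxyl, chloro, bromo, amino,
carboxyl — classic medicinal-chemistry replacements). The cores were
chosen large enough that every same-core pair clears the 50% ECFP4
similarity filter; small aromatics (toluene/phenol ≈ 0.3) would silently
fall out of the default analysis.

Endpoint values are `base(scaffold) + fragment score + N(0, noise_sd)`
with `noise_sd` 0.1 by default and scaffold bases drawn uniformly from
[0, 2] per seed. The fragment score uses the *same* additive rule as the
bundled `AdditivePredictor`: one contribution per distinct single-cut
scaffold/variable split, with multiplicity. Counting with multiplicity
(not set presence) matters twice: a core may itself contain a vocabulary
fragment (a methoxy methyl), and a substituent may contain another (the
carboxyl's hydroxyl); the contribution solver unfolds this containment so
every planted left→right replacement shifts the score by exactly its
stated effect — verified to 1e−9 in the zero-noise tests. The default
effects plant a +1.0 methyl→hydroxyl headline, a −1.0 hydrogen→carboxyl
mirror of the classic detoxifying carboxylation, and a chloro→bromo null
control. A configurable fraction of molecules carries predicted-source
values (with a stated uncertainty) instead of experimental ones.

**What passing tests show — and don't.** The library provides exact
ground truth for the *machinery*: pair finding, counting, the binomial
and Holm decisions, provenance classes, bootstrap behaviour and optimizer
accounting. It does not emulate real SAR: activity cliffs, context
dependence of replacements (the additive model has none), correlated
assay noise, scaffold diversity, or realistic hit rates. A 100%
optimizer effectiveness on planted effects is a correctness check of the
bookkeeping, not an expectation for laboratory data. One structural
consequence of the one-site design is a hard ceiling on evidence: each
planted replacement is seen in exactly one pair per scaffold, so with 10
scaffolds the sign test bottoms out at p = 0.5¹⁰ ≈ 9.8e−4 — strongly
significant, but bounded.

## Numerical and design choices

* `n_pos` is defined as the count of pairs *increasing* the property (the
  test itself only uses the min of the two counts, so the choice is a
  naming convention, documented here).
* Zero deltas (|Δ| < 1e−9) are excluded from both counts and reported
  separately.
* Two empty fingerprints have Tanimoto similarity 1.0 by convention.
* Pair records orient deterministically by (fragment notation, molecule
  id); transformation direction is fixed by the lexicographic `left ≤
  right` rule, since the direction of a replacement is otherwise
  arbitrary.
* The delta-pair chart assigns sign quadrants (+,+)=1, (−,+)=2, (−,−)=3,
  (+,−)=4 on (experimental, predicted) deltas; a zero delta goes to the
  axis-adjacent quadrant with the lower index and is flagged `on_axis`.
  Quadrants 2/4 with max(|Δ|) above the cliff threshold (default 1.0 log
  unit) are mispredicted activity cliffs.
* The transformation graph orients each edge toward the
  higher-property fragment (continuous) or the higher after-active
  fraction (binary); layout and clustering are left to DOT/GraphML
  consumers.
* The index is persisted as plain tabular files keyed by fragment
  notation — portable and diffable; no database is required.

## Known limitations

* Fragment matching in the optimizer is context-blind; products may be
  synthetically implausible.
* Multi-cut transformations with symmetric fragments can in principle
  admit several attachment pairings; all matching permutations are
  enumerated and products deduplicated, but no chemical preference is
  expressed among them.
* Binary "deactivation ratio" selection needs the paired transition
  counts, so it is only available when per-pair labels (not just margins)
  are present — always true inside this package, but relevant to external
  stats imports.
* The per-pair-side bootstrap perturbation ignores cross-pair correlation
  from shared molecules (see above).
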