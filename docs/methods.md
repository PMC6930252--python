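# Methods

This note records the models, conventions and numerical choices behind
parsalign, and what the synthetic tests do and do not demonstrate.

## The blocked-MSA dialect

A blocked MSA is standard aligned FASTA in which character case and all-gap
columns carry the whole block semantics: a column is a *spacer* iff all
gaps, *aligned* iff it contains an upper-case letter and no lower-case one,
*unaligned* in the converse case. Mixed-case columns are hard format errors
(the construction forbids them); a `lenient` flag demotes them to warnings
with majority-case classification so foreign files can still be inspected.
The gap character is `-`; `.` is accepted on input and normalised. `X`/`x`
are accepted as residues for layout purposes but excluded from profile
counts and p-distance comparisons. Maximal runs of equally classified
columns become blocks; the parser accepts any spacer width ≥ 1 (the kinase
file uses two empty columns per boundary) and the writer preserves the
column count exactly, so parse∘write and write∘parse are identities on
canonical files. Canonical form left-justifies every unaligned region:
residues first, then gaps, within the region's column range.

Aligned blocks are named from a user-supplied list (e.g. the seventeen
kinase block names B1N…HI) or auto-named A1, A2, …; unaligned regions are
named `left~right` after their flanking aligned blocks. Residue numbering
is 1-based over the domain sequence, shifted by the per-sequence domain
start from the metadata sidecar when present.

## Validation statistics

For a sequence pair, the MSA induces a residue-pair set from aligned-class
columns only; residues in unaligned columns are flagged *lower*. Against a
structure-derived pairwise alignment:

- TPR skip rule: structure pairs are dropped when either residue is
  MSA-lower (identical-length unaligned stretches would otherwise be scored
  as misalignments the MSA never claimed).
- PPV skip rule: MSA pairs are dropped when either residue is aligned to a
  gap in the structure alignment or absent from it; absence (no
  coordinates, i.e. disorder) is deliberately treated exactly like gap
  alignment. A residue that is lower-case in the structure alignment but
  faces a residue is *not* skipped; an MSA pair touching it counts as an
  error, since such positions are structurally unreliable rather than
  missing.
- Jaccard uses both retained sets: N_correct / (N_struct + N_seq −
  N_correct). This identity is asserted on every instance.

Aggregate values are unweighted means of per-pair ratios, matching a
computation that forms the ratio for each pair of sequences first; pairs
with a zero denominator are excluded from the corresponding mean and
tallied. A pooled-count mode (sum numerators and denominators before
dividing) is provided for sensitivity analysis; on the synthetic data the
two differ by well under 0.01.

Gappiness counts maximal gap runs per row. The default counts terminal
runs too (`internal_only=False`); both conventions are exposed because
published per-alignment figures do not always state the terminal-gap
convention, and the validation report records which was used.

The discrepancy profile maps each retained structure pair absent from the
MSA to the reference residue occupying the MSA column of the pair's
first-sequence residue. When neither sequence is the reference this mapping
is a design choice; a `count_both` flag maps through both residues' columns
instead. Pairs landing on reference-gap columns accumulate in an explicit
unmapped bin.

## Phylogeny

p-distance: proportion of differing residues over columns where both
sequences have non-gap, non-X residues (pairwise deletion; a
complete-deletion mode exists). Pairs with zero comparable sites are
flagged undefined and neighbor joining refuses them, directing the caller
to prune — preferable to silently imputing.

Neighbor joining is the classic Saitou–Nei agglomeration on the
Q-criterion. Ties in Q are broken by the lexicographically smallest pair of
cluster labels (each cluster keyed by its smallest member id), making the
topology deterministic. Negative branch lengths are clamped to zero with
the deficit logged at debug level. On additive matrices the algorithm
recovers the generating tree exactly; this is property-tested up to 20
leaves and cross-checked against an independent NJ implementation.

Bootstrap replicates resample columns with replacement to the original
width from a seeded generator (byte-reproducible). Transfer bootstrap
supports use the naive algorithm: for each internal reference branch, the
minimum Hamming distance between its bipartition (as a leaf bitmask) and
*every* edge of each replicate — trivial edges included, which bounds the
transfer distance by p−1. Support is 100·(1 − mean δ/(p−1)). The classical
presence/absence support is also provided; TBE dominates it branch-wise by
construction, and the suite asserts this. The naive search is quadratic in
branches per replicate and is intended for desk scale (hundreds of leaves,
hundreds to a few thousand replicates); the published kinase tree used
5000 replicates on 497 leaves, which this implementation can process but
slowly — the CLI defaults to 1000 replicates.

Newick I/O: a canonical writer (children ordered by smallest descendant
leaf label; branch lengths in shortest lossless form; supports as
internal-node labels) paired with dendropy's parser, giving byte-stable
round trips.

## Group profiles

Profiles are per-column 20-letter log-odds models in bits. Match columns
are those with ≤ 50% gaps after empty-column deletion; other columns are
dropped (no insert states — scoring handles insertions through affine gap
penalties instead). Emissions are (counts + α·q)/(n + α) with pseudocount
α = 1 and a uniform background q by default (Robinson–Robinson
frequencies optional); these mirror what a profile builder would do by
default and are configurable. Scoring is best local alignment of the
sequence to the profile columns (Smith–Waterman recurrence, gap-open
4 bits, gap-extend 0.5 bits, open ≥ extend enforced); the horizontal gap
state is evaluated with a max-prefix scan, exact whenever open ≥ extend.

Classification takes the arg-max group; a sequence passes if its best
score clears the threshold, else it stays OTHER. Because native bit scores
live on their own scale, no external tool's cutoff applies; the `auto`
threshold is the midpoint between the 5th percentile of labelled members'
own-group scores and the 95th percentile of their best *cross-group*
scores. Cross-group scores are the negative class on purpose: unassigned
sequences cannot serve as negatives since some of them may be unrecognised
members — which is exactly what the procedure is trying to find.
Reassignment runs exactly two passes (rebuild profiles with updated labels
once and rescore), is idempotent on consistent labelings, and logs every
label change.

## Synthetic families

The generator emulates the structure of the kinase alignment: a root
consensus over aligned blocks (defaults: the seventeen deposited block
lengths), per-group consensus divergence, per-sequence within-group
substitution (uniform exchange by default; a background-weighted option
exists), and per-region geometric insertion lengths (defaults: the
deposited per-region medians, zero-length insertions included), emitted
lower-case and left-justified with two-column spacers. Default family
shape is 4 groups × 25 sequences; the classification study condition is 2
groups at 40% inter-group/10% within-group divergence. Everything is
reproducible from a single seed.

Structure-alignment noise has two components chosen to mimic how real
structure alignments fail: *disorder* (each residue independently dropped
with probability 0.05 by default; its partner becomes gap-aligned) and
*shifts* (per aligned block, probability 0.1 of displacing a random
sub-run of pairs by ±1, with colliding or out-of-range pairs removed).
The perturbation ledger records every event, so per-pair TPR/PPV/Jaccard
have closed-form expected values; the suite asserts the full
induction-and-scoring pipeline equals them to 1e-12.

What the synthetic data does *not* capture: realistic substitution
processes (no rate matrix, no site heterogeneity), phylogenetically
correlated indels, gaps inside aligned blocks (the kinase alignment has a
few), multi-column shifts, and the long-tailed insertion lengths of real
kinases (the 548-residue activation-loop insertion of MASTL is far beyond
a geometric tail). Passing tests therefore demonstrate correctness of the
statistics and procedures, not biological realism; the published kinase
values are checked separately against the deposited data when available
(see README).

## Problem sizes

The default test and acceptance runs use families of 10–100 sequences,
trees of 6–40 leaves, 100–200 bootstrap replicates, and 200 randomised
validation instances; these sizes exercise every code path while keeping
the whole suite in seconds. The published-scale computation (497 taxa,
5000 replicates, 36,856 benchmark pairs) runs through the same entry
points and is documented in the README rather than executed by default.
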