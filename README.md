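# parsalign

Tools for **parsimonious, blocked multiple sequence alignments** of protein
domain families — the alignment style used for the human protein kinase
domain family, where the alignment is arranged as upper-case **aligned
blocks** (structurally conserved elements: helices, strands, the DFG/HRD/APE
motif regions) separated by lower-case, left-justified **unaligned regions**
holding lineage-specific insertions, with all-gap spacer columns in between.

The package is for sequence analysts who work with such alignments and need
to (a) parse and describe them, (b) *validate* them against pairwise
structure alignments, (c) build block-based phylogenies with robust branch
supports, and (d) classify sequences into groups with per-group profiles.

## What it computes

**Structural validation.** For each pair of sequences present in both the
MSA and a structure-derived benchmark alignment, with N_correct the residue
pairs aligned in both:

- **TPR** = N_correct / N_struct (the "developer" score *f*<sub>D</sub>),
  where structure pairs touching a lower-case MSA residue are skipped — the
  MSA makes no homology claim there;
- **PPV** = N_correct / N_seq (the "modeler" score *f*<sub>M</sub>), where
  MSA pairs whose residues are gap-aligned or absent (disordered) in the
  structure alignment are skipped;
- **Jaccard** = N_correct / (N_struct + N_seq − N_correct), penalising both
  over- and under-alignment;
- **gappiness**: the mean number of maximal gap runs per sequence.

**Phylogeny.** Unaligned regions are deleted, p-distances are computed over
mutually ungapped columns, a tree is built with neighbor joining
(Saitou–Nei), and branch robustness is measured on column-bootstrap
replicates with the **transfer bootstrap expectation**,
support = 100·(1 − mean δ/(p−1)), δ the minimum transfer distance of the
branch's bipartition to each replicate and p its lighter-side size.

**Group profiles.** Per-group position-specific log-odds models (bits,
pseudocount-smoothed, ≤50%-gap match columns) scored by best local
alignment with affine gap penalties; a two-pass procedure reassigns
unclassified ("OTHER") sequences whose best score clears a recalibrated
threshold.

**Synthetic families.** A seeded generator produces blocked families with
known residue-level ground truth plus perturbed "structure alignments"
(disorder and shifted-element noise) with closed-form expected scores, so
the whole pipeline is testable without downloads.

## Worked example

```python
from parsalign import *
from parsalign.synthetic import (FamilySpec, generate_blocked_family,
                                 simulate_structure_alignments)

fam = generate_blocked_family(FamilySpec(n_groups=2, seqs_per_group=5, seed=42))
print(fam.msa)                       # BlockedMSA(10 sequences x 382 columns)

alns, _ = simulate_structure_alignments(fam, seed=1)
report = validate_msa(fam.msa, alns.values())
print(report.summary())
# {'n_pairs': 45, 'mean_tpr': 0.967, 'mean_ppv': 0.977,
#  'mean_jaccard': 0.947, 'gappiness': 19.3, 'aggregation': 'mean', ...}

table = block_statistics(fam.msa, fam.ids[0])
print(table.unaligned.head(3))
# region  col_start  col_end  median_length  max_length longest_in
#  A3~A4         27       34            3.0           8  G2_seq005
#  A4~A5         50       86           10.5          37  G1_seq002
#  A8~A9        146      152            0.0           7  G2_seq002
```

The validation means read as: at the generator's default noise rates (5%
disordered residues, 10% per-block shift probability), the blocked MSA
recovers 96.7% of the structure-aligned pairs, 97.7% of its own pairs are
confirmed, and the retained pair sets overlap with Jaccard 0.947 — the
shifted elements account for the whole deficit, as the per-pair ledger
shows. Tree building continues from the same objects:

```python
plain = extract_aligned_columns(fam.msa)        # blocks only
tree = neighbor_joining(p_distance_matrix(plain))
reps = [neighbor_joining(p_distance_matrix(r))
        for r in bootstrap_columns(plain, 100, seed=17)]
transfer_support(tree, reps)
print(write_newick(tree))           # supports as internal-node labels
```

A `parsalign` console command exposes the same stages
(`simulate`, `blocks`, `validate`, `tree`, `classify`); try
`parsalign --help`.

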