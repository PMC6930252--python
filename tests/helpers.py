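"""Shared test utilities: independent oracles and random instance generators.

The oracles here re-derive results from first principles (naive column
walks, explicit set materialisation, exhaustive searches) so the library
path they check is never the code that computes the expected value.
"""

from __future__ import annotations

import dendropy
import numpy as np

from parsalign.pairdata import PairwiseAlignment
from parsalign.synthetic import FamilySpec, generate_blocked_family, simulate_structure_alignments

GAP = "-"


# ---------------------------------------------------------------------- #
# naive pair-score oracle (column walk + explicit sets)


def oracle_pair_scores(row_a: str, row_b: str, struct: PairwiseAlignment):
    """(n_correct, n_struct, n_seq) recomputed naively from the raw MSA rows.

    Column classes, induced pairs, lower flags and both skip rules are
    re-derived here with plain loops, independent of the library's
    induced_pair_set / pair_scores implementations.
    """
    # classify columns of the 2-row alignment
    classes = []
    for ca, cb in zip(row_a, row_b):
        chars = [c for c in (ca, cb) if c != GAP]
        if not chars:
            classes.append("spacer")
        elif any(c.islower() for c in chars):
            assert not any(c.isupper() for c in chars)
            classes.append("unaligned")
        else:
            classes.append("aligned")
    # walk columns: induced pairs and lower sets
    msa_pairs, low_a, low_b = set(), set(), set()
    ra = rb = 0
    for (ca, cb), kind in zip(zip(row_a, row_b), classes):
        if ca != GAP:
            ra += 1
            if kind == "unaligned":
                low_a.add(ra)
        if cb != GAP:
            rb += 1
            if kind == "unaligned":
                low_b.add(rb)
        if kind == "aligned" and ca != GAP and cb != GAP:
            msa_pairs.add((ra, rb))
    # TPR skip rule
    retained_struct = set()
    for a, b in struct.pairs:
        if a in low_a or b in low_b:
            continue
        retained_struct.add((a, b))
    # PPV skip rule
    retained_seq = set()
    for a, b in msa_pairs:
        if a not in struct.covered_a or b not in struct.covered_b:
            continue
        if a in struct.gap_opposed_a or b in struct.gap_opposed_b:
            continue
        retained_seq.add((a, b))
    n_correct = len(retained_struct & retained_seq)
    return n_correct, len(retained_struct), len(retained_seq)


def random_validation_instance(seed: int):
    """A small 2-sequence family plus one noisy structure alignment."""
    rng = np.random.default_rng(seed)
    n_blocks = int(rng.integers(2, 5))
    spec = FamilySpec(
        n_groups=1,
        seqs_per_group=2,
        block_lengths=tuple(int(rng.integers(2, 7)) for _ in range(n_blocks)),
        insertion_means=tuple(float(rng.uniform(0, 3)) for _ in range(n_blocks - 1)),
        group_divergence=0.0,
        within_divergence=float(rng.uniform(0, 0.4)),
        seed=int(rng.integers(2**31)),
    )
    sample = generate_blocked_family(spec)
    id_a, id_b = sample.ids
    alns, ledgers = simulate_structure_alignments(
        sample,
        disorder_rate=float(rng.uniform(0, 0.3)),
        shift_rate=float(rng.uniform(0, 0.6)),
        seed=int(rng.integers(2**31)),
    )
    return sample, alns[(id_a, id_b)], ledgers[(id_a, id_b)]


# ---------------------------------------------------------------------- #
# self-consistent structure alignments (struct := MSA's own induced pairs)


def struct_from_induced(rps, len_a: int, len_b: int) -> PairwiseAlignment:
    return PairwiseAlignment(
        rps.id_a,
        rps.id_b,
        rps.pairs,
        frozenset(range(1, len_a + 1)),
        frozenset(range(1, len_b + 1)),
        rps.lower_a,
        rps.lower_b,
    )


# ---------------------------------------------------------------------- #
# random trees and additive matrices


def random_tree(labels, rng: np.random.Generator) -> dendropy.Tree:
    """Random unrooted binary-ish tree with uniform branch lengths."""
    nodes = [dendropy.Node(taxon=dendropy.Taxon(lab)) for lab in labels]
    tns = dendropy.TaxonNamespace([n.taxon for n in nodes])
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for n in (nodes[i], nodes[j]):
            n.edge.length = float(rng.uniform(0.02, 0.2))
            parent.add_child(n)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        n.edge.length = float(rng.uniform(0.02, 0.2))
        root.add_child(n)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_patristic_matrix(tree: dendropy.Tree):
    """(ids, matrix) of leaf-to-leaf path distances, scaled into [0, 1]."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    ids = tuple(sorted(taxa))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
    scale = d.max()
    if scale > 1.0:
        d = d / (scale * 1.01)
    return ids, d


def oracle_transfer_distance(ref_leafset: frozenset, tree: dendropy.Tree) -> int:
    """Brute-force minimum transfer distance via frozenset symmetric differences."""
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    best = len(all_leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        h = len(ref_leafset ^ side)
        best = min(best, h, len(all_leaves) - h)
    return best
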