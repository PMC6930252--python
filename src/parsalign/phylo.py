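"""Block-based phylogeny: p-distance, neighbor joining, bootstrap, TBE.

The tree pipeline mirrors how a blocked MSA is meant to be used for
phylogenetics: unaligned regions are deleted (``extract_aligned_columns``),
pairwise p-distances are computed over mutually ungapped columns, a tree is
built with classic neighbor joining (Saitou-Nei, Q-criterion), and branch
robustness is quantified on column-bootstrap replicates with the transfer
bootstrap expectation (TBE): for a branch with lighter-side size p,

    support = 100 * (1 - mean over replicates of delta / (p - 1))

where delta is the minimum transfer (Hamming) distance between the branch's
bipartition and any bipartition of the replicate, under the better of the
two labelings. The transfer distance is found by exhaustive search over
replicate branches — adequate at desk scale. Classical presence/absence
bootstrap supports are also available; TBE is never smaller branch-wise.

Trees are :class:`dendropy.Tree` objects; Newick serialisation is a small
canonical writer (children sorted by smallest leaf label, shortest lossless
branch-length formatting, supports as internal-node labels) paired with
dendropy's parser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

_MISSING = frozenset("-X")  # ignored in p-distance comparisons


# ---------------------------------------------------------------------- #
# distance matrix


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in [0, 1].

    Entries with no comparable sites are NaN (flagged undefined).
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmax(v, initial=0.0) > 1.0 + 1e-12 or np.nanmin(v, initial=0.0) < 0.0:
            raise ValueError("p-distances must lie in [0, 1]")

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = self.ids.index(key[0]), self.ids.index(key[1])
        return float(self.values[i, j])

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_tsv(self) -> str:
        lines = ["\t".join(("",) + self.ids)]
        for i, sid in enumerate(self.ids):
            lines.append(
                sid + "\t" + "\t".join(repr(float(x)) for x in self.values[i])
            )
        return "\n".join(lines) + "\n"


def p_distance_matrix(
    records: Mapping[str, str], deletion: str = "pairwise"
) -> DistanceMatrix:
    """Proportion of differing residues over comparable columns, per pair.

    Case-insensitive; gap and 'X' positions are excluded. ``deletion`` is
    ``"pairwise"`` (sites with residues in both sequences of the pair) or
    ``"complete"`` (sites with residues in every sequence). A pair with zero
    comparable sites gets NaN.
    """
    ids = tuple(records)
    rows = [records[s].upper() for s in ids]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("p-distance requires equal-length sequences")
    arr = np.array([list(r) for r in rows])
    valid = ~np.isin(arr, list(_MISSING))
    if deletion == "complete":
        keep = valid.all(axis=0)
        arr, valid = arr[:, keep], valid[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & both
        n_comp = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(n_comp > 0, diff.sum(axis=1) / np.maximum(n_comp, 1), np.nan)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return DistanceMatrix(ids, out)


# ---------------------------------------------------------------------- #
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining with a deterministic tie-break.

    When several (i, j) minimise the Q-criterion, the pair whose sorted
    lexicographically-smallest member labels come first wins. Negative
    branch lengths are clamped to 0 (deficit logged). Undefined distances
    are an error; prune or impute first.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.has_undefined:
        raise ValueError(
            "distance matrix has undefined entries; prune or impute those taxa"
        )
    tns = dendropy.TaxonNamespace([str(s) for s in dm.ids])
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # lexicographic tie-break key = smallest member label
    for sid in dm.ids:
        node = dendropy.Node(taxon=tns.get_taxon(str(sid)))
        nodes.append(node)
        keys.append(str(sid))
    d = dm.values.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative NJ branch length %g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, i, j = min(candidates)
        vi = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(vi)
        nodes[j].edge.length = clamp(vj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = (d[i] + d[j] - d[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final 3-way join: closed-form star lengths
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    root = dendropy.Node()
    a.edge.length = clamp((dab + dac - dbc) / 2)
    b.edge.length = clamp((dab + dbc - dac) / 2)
    c.edge.length = clamp((dac + dbc - dab) / 2)
    for node in (a, b, c):
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------- #
# bootstrap replicates


def bootstrap_columns(
    records: Mapping[str, str], n_replicates: int, seed: int
) -> Iterable[dict[str, str]]:
    """Yield column-bootstrap replicates of an aligned input.

    Each replicate samples columns with replacement to the original width;
    the stream is fully reproducible from ``seed``.
    """
    ids = list(records)
    rows = [records[s] for s in ids]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("bootstrap requires an aligned (equal-length) input")
    n_col = len(rows[0])
    arr = np.array([list(r) for r in rows])
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_col, size=n_col)
        sub = arr[:, cols]
        yield {sid: "".join(sub[i]) for i, sid in enumerate(ids)}


# ---------------------------------------------------------------------- #
# bipartitions and branch supports


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _edge_masks(
    tree: dendropy.Tree, index: Mapping[str, int]
) -> list[tuple[dendropy.Node, int]]:
    """(node, bitmask of the leaf set below the node's edge) for every edge."""
    masks: list[tuple[dendropy.Node, int]] = []
    mask_of: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            m = 1 << index[node.taxon.label]
        else:
            m = 0
            for child in node.child_nodes():
                m |= mask_of[id(child)]
        mask_of[id(node)] = m
        if node.parent_node is not None:
            masks.append((node, m))
    return masks


def nontrivial_bipartitions(
    tree: dendropy.Tree, index: Mapping[str, int] | None = None
) -> frozenset[int]:
    """Normalised bitmasks of the tree's internal-edge bipartitions.

    Masks are normalised to the side not containing taxon 0 so the same
    split always yields the same integer.
    """
    if index is None:
        index = {lab: i for i, lab in enumerate(sorted(leaf_labels(tree)))}
    n = len(index)
    full = (1 << n) - 1
    out = set()
    for _, m in _edge_masks(tree, index):
        size = m.bit_count()
        if 1 < size < n - 1:
            out.add(m ^ full if m & 1 else m)
    return frozenset(out)


def transfer_distance(mask: int, other_masks: Sequence[int], n_leaves: int) -> int:
    """Minimum transfer distance from a bipartition to any branch of a tree.

    ``other_masks`` must include every edge of the other tree (trivial
    leaf edges too), which bounds the result by p - 1.
    """
    best = n_leaves
    for c in other_masks:
        h = (mask ^ c).bit_count()
        best = min(best, h, n_leaves - h)
        if best == 0:
            break
    return best


def transfer_support(
    ref_tree: dendropy.Tree, replicate_trees: Iterable[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate internal branches of ``ref_tree`` with TBE supports in [0, 100].

    All trees must share the reference's leaf set. Supports are stored as
    ``node.support`` (float) and as the internal-node label (for Newick);
    leaf branches carry no support.
    """
    labels = sorted(leaf_labels(ref_tree))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    full = (1 << n) - 1

    internal: list[tuple[dendropy.Node, int, int]] = []
    for node, m in _edge_masks(ref_tree, index):
        size = m.bit_count()
        if 1 < size < n - 1:
            p = min(size, n - size)
            internal.append((node, m, p))
    deficits = [0.0] * len(internal)

    n_rep = 0
    for rep in replicate_trees:
        if leaf_labels(rep) != frozenset(labels):
            raise ValueError("replicate tree leaf set differs from reference")
        rep_masks = [m for _, m in _edge_masks(rep, index)]
        n_rep += 1
        for k, (_, m, p) in enumerate(internal):
            deficits[k] += transfer_distance(m, rep_masks, n) / (p - 1)
    if n_rep == 0:
        raise ValueError("no replicate trees supplied")

    for k, (node, _, _) in enumerate(internal):
        support = 100.0 * (1.0 - deficits[k] / n_rep)
        node.support = support
        node.label = format(support, ".6g")
    return ref_tree


def classical_support(
    ref_tree: dendropy.Tree, replicate_trees: Iterable[dendropy.Tree]
) -> dict[int, float]:
    """Presence/absence bootstrap support per internal branch.

    Returns {normalised bipartition mask: percent of replicates containing
    that exact split}.
    """
    labels = sorted(leaf_labels(ref_tree))
    index = {lab: i for i, lab in enumerate(labels)}
    ref_bips = nontrivial_bipartitions(ref_tree, index)
    hits = {m: 0 for m in ref_bips}
    n_rep = 0
    for rep in replicate_trees:
        n_rep += 1
        rep_bips = nontrivial_bipartitions(rep, index)
        for m in ref_bips:
            if m in rep_bips:
                hits[m] += 1
    if n_rep == 0:
        raise ValueError("no replicate trees supplied")
    return {m: 100.0 * h / n_rep for m, h in hits.items()}


def support_by_bipartition(tree: dendropy.Tree) -> dict[int, float]:
    """{normalised bipartition mask: support} for annotated internal branches."""
    labels = sorted(leaf_labels(tree))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    full = (1 << n) - 1
    out = {}
    for node, m in _edge_masks(tree, index):
        if 1 < m.bit_count() < n - 1 and getattr(node, "support", None) is not None:
            out[m ^ full if m & 1 else m] = float(node.support)
    return out


# ---------------------------------------------------------------------- #
# Newick I/O


def _format_length(length: float | None) -> str:
    if length is None:
        return ""
    x = float(length)
    if x == int(x):
        return f":{int(x)}"
    return f":{x!r}"


def write_newick(tree: dendropy.Tree, canonical: bool = True) -> str:
    """Serialise to Newick with supports as internal-node labels.

    With ``canonical`` the children of every node are ordered by their
    smallest descendant leaf label, making the output unique for a given
    (unrooted) topology, branch lengths and supports.
    """

    def rec(node: dendropy.Node) -> tuple[str, str]:
        if node.is_leaf():
            lab = node.taxon.label if node.taxon else (node.label or "")
            return lab, lab + _format_length(node.edge.length)
        parts = [rec(c) for c in node.child_nodes()]
        if canonical:
            parts.sort(key=lambda t: t[0])
        min_leaf = min(t[0] for t in parts)
        body = "(" + ",".join(t[1] for t in parts) + ")" + (node.label or "")
        return min_leaf, body + _format_length(node.edge.length)

    return rec(tree.seed_node)[1] + ";"


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text (underscores preserved, internal labels kept).

    Internal-node labels that parse as numbers are mirrored into
    ``node.support``. Malformed input raises a parse error carrying the
    offending position.
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree
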