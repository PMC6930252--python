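"""Residue-level pairwise alignments.

Two sources produce the same in-memory currency:

* *structure-derived* pairwise alignments (SE-style two-record case-encoded
  FASTA, where upper case marks structurally reliable positions), parsed by
  :func:`parse_case_pairwise`;
* alignments *induced* between any two rows of a blocked MSA
  (:func:`induced_pair_set`): only aligned-class (upper-case) columns induce
  residue pairs.

Residue indices are 1-based over the domain sequence. Residues absent from a
structure (disordered, no coordinates) are simply absent from the covered
sets; parsers never invent pairs for them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .blockmsa import ALIGNED, GAP, UNALIGNED, BlockedMSA


class PairwiseFormatError(ValueError):
    pass


def _check_partial_matching(pairs: Iterable[tuple[int, int]]) -> None:
    seen_a: set[int] = set()
    seen_b: set[int] = set()
    for a, b in pairs:
        if a in seen_a or b in seen_b:
            raise ValueError(
                f"pair set is not a partial matching: residue reused in ({a}, {b})"
            )
        seen_a.add(a)
        seen_b.add(b)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A structure-derived pairwise alignment between sequences A and B.

    ``pairs`` holds the (upper-case) aligned residue-index pairs and is a
    partial matching. ``covered_*`` are all residue indices present in the
    alignment at all; ``lower_*`` the ones printed in lower case (low
    structural similarity); ``gap_opposed_*`` the covered residues facing a
    gap character — together these drive the validation skip rules.
    """

    id_a: str
    id_b: str
    pairs: frozenset[tuple[int, int]]
    covered_a: frozenset[int]
    covered_b: frozenset[int]
    lower_a: frozenset[int] = frozenset()
    lower_b: frozenset[int] = frozenset()
    gap_opposed_a: frozenset[int] = frozenset()
    gap_opposed_b: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        _check_partial_matching(self.pairs)
        for a, b in self.pairs:
            if a not in self.covered_a or b not in self.covered_b:
                raise ValueError(f"pair ({a}, {b}) outside covered residue sets")
            if a in self.lower_a or b in self.lower_b:
                raise ValueError(
                    f"lower-case residue participates in aligned pair ({a}, {b})"
                )

    @property
    def matched_a(self) -> frozenset[int]:
        return frozenset(a for a, _ in self.pairs)

    @property
    def matched_b(self) -> frozenset[int]:
        return frozenset(b for _, b in self.pairs)

    def transpose(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            self.id_b,
            self.id_a,
            frozenset((b, a) for a, b in self.pairs),
            self.covered_b,
            self.covered_a,
            self.lower_b,
            self.lower_a,
            self.gap_opposed_b,
            self.gap_opposed_a,
        )


@dataclass(frozen=True)
class ResiduePairSet:
    """The residue pairs induced between two rows of a blocked MSA.

    ``lower_a``/``lower_b`` flag residues lying in unaligned-class columns;
    such residues never participate in pairs.
    """

    id_a: str
    id_b: str
    pairs: frozenset[tuple[int, int]]
    lower_a: frozenset[int] = frozenset()
    lower_b: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        _check_partial_matching(self.pairs)
        for a, b in self.pairs:
            if a in self.lower_a or b in self.lower_b:
                raise ValueError(
                    f"lower-flagged residue participates in pair ({a}, {b})"
                )

    def transpose(self) -> "ResiduePairSet":
        return ResiduePairSet(
            self.id_b,
            self.id_a,
            frozenset((b, a) for a, b in self.pairs),
            self.lower_b,
            self.lower_a,
        )


# ---------------------------------------------------------------------- #
# parsing


def parse_case_pairwise(
    text: str, start_a: int = 1, start_b: int = 1
) -> PairwiseAlignment:
    """Parse a two-record case-encoded aligned FASTA into a PairwiseAlignment.

    Columns where both characters are upper case yield pairs; lower-case
    residues and residues opposite gaps are recorded in the lower/covered/
    gap-opposed sets. ``start_a``/``start_b`` offset residue numbering.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    entries = list(SimpleFastaParser(io.StringIO(text)))
    if len(entries) != 2:
        raise PairwiseFormatError(
            f"pairwise alignment must have exactly 2 records, found {len(entries)}"
        )
    (title_a, row_a), (title_b, row_b) = entries
    row_a = row_a.replace(".", GAP)
    row_b = row_b.replace(".", GAP)
    if len(row_a) != len(row_b):
        raise PairwiseFormatError("pairwise alignment rows differ in length")
    id_a, id_b = title_a.split()[0], title_b.split()[0]

    pairs, cov_a, cov_b = set(), set(), set()
    low_a, low_b, gapo_a, gapo_b = set(), set(), set(), set()
    ra, rb = start_a - 1, start_b - 1
    for ca, cb in zip(row_a, row_b):
        if ca != GAP:
            ra += 1
            cov_a.add(ra)
            if ca.islower():
                low_a.add(ra)
            if cb == GAP:
                gapo_a.add(ra)
        if cb != GAP:
            rb += 1
            cov_b.add(rb)
            if cb.islower():
                low_b.add(rb)
            if ca == GAP:
                gapo_b.add(rb)
        if ca != GAP and cb != GAP and ca.isupper() and cb.isupper():
            pairs.add((ra, rb))
    return PairwiseAlignment(
        id_a,
        id_b,
        frozenset(pairs),
        frozenset(cov_a),
        frozenset(cov_b),
        frozenset(low_a),
        frozenset(low_b),
        frozenset(gapo_a),
        frozenset(gapo_b),
    )


def induced_pair_set(msa: BlockedMSA, id_a: str, id_b: str) -> ResiduePairSet:
    """Residue pairs induced between two MSA rows by aligned-class columns.

    For every aligned-class column where both rows carry residues a pair is
    emitted; residues of either row lying in unaligned-class columns are
    flagged lower. Residue numbering honours per-row domain starts.
    """
    for sid in (id_a, id_b):
        if sid not in msa.records:
            raise KeyError(f"unknown sequence id {sid!r}")
    row_a, row_b = msa.records[id_a], msa.records[id_b]
    classes = msa.column_classes
    ra, rb = msa.start_of(id_a) - 1, msa.start_of(id_b) - 1
    pairs, low_a, low_b = set(), set(), set()
    for c in range(len(row_a)):
        ca, cb = row_a[c], row_b[c]
        kind = classes[c]
        if ca != GAP:
            ra += 1
            if kind == UNALIGNED:
                low_a.add(ra)
        if cb != GAP:
            rb += 1
            if kind == UNALIGNED:
                low_b.add(rb)
        if kind == ALIGNED and ca != GAP and cb != GAP:
            pairs.add((ra, rb))
    return ResiduePairSet(
        id_a, id_b, frozenset(pairs), frozenset(low_a), frozenset(low_b)
    )


# ---------------------------------------------------------------------- #
# conservation profile


def reference_conservation(
    alignments: Iterable[PairwiseAlignment],
    reference_id: str,
    reference_length: int,
    start: int = 1,
) -> np.ndarray:
    """Count, per reference residue, how often it joins an aligned pair.

    ``count[i]`` is the number of alignments in which reference residue
    ``start + i`` participates in an upper-case pair. Every alignment must
    contain ``reference_id`` on either side.
    """
    counts = np.zeros(reference_length, dtype=int)
    for aln in alignments:
        if aln.id_a == reference_id:
            members = aln.matched_a
        elif aln.id_b == reference_id:
            members = aln.matched_b
        else:
            raise ValueError(
                f"alignment {aln.id_a}/{aln.id_b} does not contain "
                f"reference {reference_id!r}"
            )
        for r in members:
            i = r - start
            if 0 <= i < reference_length:
                counts[i] += 1
    return counts


# ---------------------------------------------------------------------- #
# generic pair-list TSV interchange

_TSV_HEADER = "id_a\tres_a\tid_b\tres_b\tflag"


def write_pair_tsv(aln: PairwiseAlignment) -> str:
    """Serialize an alignment as a pair-list TSV.

    Aligned pairs get flag ``pair``; unpaired covered residues are emitted
    one-sided with a comma-joined subset of ``lower``/``gap``/``covered`` so
    the alignment round-trips exactly.
    """

    def flags(r: int, lower: frozenset, gap_opposed: frozenset) -> str:
        out = []
        if r in lower:
            out.append("lower")
        if r in gap_opposed:
            out.append("gap")
        return ",".join(out) or "covered"

    lines = [_TSV_HEADER]
    for a, b in sorted(aln.pairs):
        lines.append(f"{aln.id_a}\t{a}\t{aln.id_b}\t{b}\tpair")
    for a in sorted(aln.covered_a - aln.matched_a):
        lines.append(
            f"{aln.id_a}\t{a}\t{aln.id_b}\t.\t{flags(a, aln.lower_a, aln.gap_opposed_a)}"
        )
    for b in sorted(aln.covered_b - aln.matched_b):
        lines.append(
            f"{aln.id_a}\t.\t{aln.id_b}\t{b}\t{flags(b, aln.lower_b, aln.gap_opposed_b)}"
        )
    return "\n".join(lines) + "\n"


def read_pair_tsv(text: str) -> PairwiseAlignment:
    """Parse the pair-list TSV dialect written by :func:`write_pair_tsv`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _TSV_HEADER:
        raise PairwiseFormatError("missing pair-list TSV header")
    id_a = id_b = None
    pairs, cov_a, cov_b = set(), set(), set()
    low_a, low_b, gapo_a, gapo_b = set(), set(), set(), set()
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != 5:
            raise PairwiseFormatError(f"malformed pair-list line: {ln!r}")
        ia, ra, ib, rb, flag = fields
        id_a, id_b = ia, ib
        if flag == "pair":
            a, b = int(ra), int(rb)
            pairs.add((a, b))
            cov_a.add(a)
            cov_b.add(b)
        else:
            marks = set(flag.split(","))
            if ra != ".":
                a = int(ra)
                cov_a.add(a)
                if "lower" in marks:
                    low_a.add(a)
                if "gap" in marks:
                    gapo_a.add(a)
            else:
                b = int(rb)
                cov_b.add(b)
                if "lower" in marks:
                    low_b.add(b)
                if "gap" in marks:
                    gapo_b.add(b)
    if id_a is None:
        raise PairwiseFormatError("empty pair-list TSV")
    return PairwiseAlignment(
        id_a,
        id_b,
        frozenset(pairs),
        frozenset(cov_a),
        frozenset(cov_b),
        frozenset(low_a),
        frozenset(low_b),
        frozenset(gapo_a),
        frozenset(gapo_b),
    )


def load_pairwise(text: str) -> PairwiseAlignment:
    """Normalise external pairwise-alignment text into a PairwiseAlignment.

    Accepts the two dialects this package understands: two-record
    case-encoded FASTA, and the pair-list TSV. This is the import adapter —
    the normalised :class:`PairwiseAlignment` is the only internal currency.
    """
    stripped = text.lstrip()
    if stripped.startswith(">"):
        return parse_case_pairwise(text)
    return read_pair_tsv(text)
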