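"""Case-encoded blocked multiple sequence alignments.

A *blocked* MSA is an aligned FASTA in which character case carries the
alignment semantics: upper-case columns form *aligned blocks* (structurally
conserved elements claimed to be homologous column-wise), lower-case columns
form *unaligned regions* (left-justified, lineage-specific insertions with no
column-wise homology claim), and all-gap columns are *spacers* separating the
two.  The deposited human kinase-domain alignment that motivated this package
uses 17 aligned blocks (B1N ... HI) and 16 unaligned regions in this dialect.

This module is the single source of truth for that file grammar: parsing,
validation, canonical writing (left-justification of unaligned regions),
column classification, block detection, column/residue coordinate maps, and
the descriptive block statistics (per-block lengths, reference residue
ranges, insertion-length medians and maxima).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

GAP = "-"

#: column classes
ALIGNED = "aligned"
UNALIGNED = "unaligned"
SPACER = "spacer"


class BlockedMSAFormatError(ValueError):
    """Raised when text does not conform to the blocked-MSA grammar."""


@dataclass(frozen=True)
class Block:
    """One maximal run of equally-classified columns.

    ``start``/``end`` are 1-based inclusive column indices.
    """

    name: str
    kind: str  # ALIGNED | UNALIGNED | SPACER
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def columns(self) -> range:
        """0-based column indices of this block."""
        return range(self.start - 1, self.end)


@dataclass(frozen=True)
class BlockLayout:
    """Ordered partition of the columns into blocks."""

    blocks: tuple[Block, ...]

    @property
    def aligned(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == ALIGNED)

    @property
    def unaligned(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == UNALIGNED)

    @property
    def n_columns(self) -> int:
        return self.blocks[-1].end if self.blocks else 0

    def __iter__(self):
        return iter(self.blocks)


class BlockedMSA:
    """An in-memory blocked MSA.

    Parameters
    ----------
    records:
        Ordered mapping sequence-id -> gapped row string. All rows must have
        equal length; non-gap characters must be letters; no column may mix
        upper- and lower-case characters (unless ``lenient``).
    metadata:
        Optional per-sequence table indexed by sequence id. Recognised
        columns: ``group``, ``gene``, ``start``, ``end``, ``accession``.
        ``start`` is the residue number of the first domain residue in the
        source protein and offsets all residue numbering for that row.
    names:
        Optional list of names for the aligned blocks, applied in order
        (e.g. the 17 kinase block names B1N ... HI).
    lenient:
        Demote mixed-case columns from errors to warnings; such columns are
        classified by majority case.
    """

    def __init__(
        self,
        records: Mapping[str, str],
        metadata: pd.DataFrame | None = None,
        names: Sequence[str] | None = None,
        lenient: bool = False,
    ) -> None:
        self.records: dict[str, str] = {
            str(sid): row.replace(".", GAP) for sid, row in records.items()
        }
        if not self.records:
            raise BlockedMSAFormatError("empty alignment: no sequences")
        if len(self.records) != len(records):
            raise BlockedMSAFormatError("duplicate sequence ids")
        lengths = {len(r) for r in self.records.values()}
        if len(lengths) > 1:
            bad = next(
                sid
                for sid, r in self.records.items()
                if len(r) != len(next(iter(self.records.values())))
            )
            raise BlockedMSAFormatError(
                f"unequal row lengths (offending id: {bad!r}); got lengths {sorted(lengths)}"
            )
        for sid, row in self.records.items():
            for ch in row:
                if ch != GAP and not ch.isalpha():
                    raise BlockedMSAFormatError(
                        f"non-amino-acid symbol {ch!r} in sequence {sid!r}"
                    )
        self.metadata = metadata
        self._names = tuple(names) if names is not None else None
        self._lenient = bool(lenient)
        self._classes: list[str] | None = None
        self._layout: BlockLayout | None = None

    # ------------------------------------------------------------------ #

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def column_classes(self) -> list[str]:
        if self._classes is None:
            self._classes = classify_columns(self.records, lenient=self._lenient)
        return self._classes

    @property
    def layout(self) -> BlockLayout:
        if self._layout is None:
            self._layout = detect_blocks(self.column_classes, names=self._names)
        return self._layout

    def sequence(self, seqid: str) -> str:
        """Ungapped sequence for one row (case preserved)."""
        return self.records[seqid].replace(GAP, "")

    def start_of(self, seqid: str) -> int:
        """Domain start residue number from metadata (1 when absent)."""
        if self.metadata is not None and seqid in self.metadata.index:
            start = self.metadata.loc[seqid].get("start")
            if start is not None and not pd.isna(start):
                return int(start)
        return 1

    def __eq__(self, other) -> bool:
        return isinstance(other, BlockedMSA) and self.records == other.records

    def __repr__(self) -> str:
        return f"BlockedMSA({self.n_sequences} sequences x {self.n_columns} columns)"


# ---------------------------------------------------------------------- #
# parsing / writing


def parse_blocked_msa(
    text: str,
    metadata: pd.DataFrame | None = None,
    names: Sequence[str] | None = None,
    lenient: bool = False,
) -> BlockedMSA:
    """Parse case-encoded aligned FASTA text into a :class:`BlockedMSA`.

    ``'.'`` gaps are normalised to ``'-'``. Raises
    :class:`BlockedMSAFormatError` on ragged rows, non-letter residue symbols
    or mixed-case columns.
    """
    records: dict[str, str] = {}
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        sid = title.split()[0]
        if sid in records:
            raise BlockedMSAFormatError(f"duplicate sequence id {sid!r}")
        records[sid] = seq.replace(".", GAP)
    msa = BlockedMSA(records, metadata=metadata, names=names, lenient=lenient)
    msa.layout  # force validation of column classes now
    return msa


def write_blocked_msa(msa: BlockedMSA, width: int = 0) -> str:
    """Write canonical case-encoded aligned FASTA.

    Canonical form left-justifies every unaligned region (residues first,
    then gaps within the region's column range); aligned and spacer columns
    are emitted verbatim, so ``parse(write(m)) == m`` and ``write(parse(t))
    == t`` for already-canonical ``t``.  ``width`` > 0 wraps sequence lines.
    """
    unaligned_blocks = [b for b in msa.layout.blocks if b.kind == UNALIGNED]
    out = []
    for sid, row in msa.records.items():
        chars = list(row)
        for b in unaligned_blocks:
            seg = row[b.start - 1 : b.end]
            residues = seg.replace(GAP, "")
            chars[b.start - 1 : b.end] = residues + GAP * (b.length - len(residues))
        body = "".join(chars)
        if width > 0:
            body = "\n".join(body[i : i + width] for i in range(0, len(body), width))
        out.append(f">{sid}\n{body}\n")
    return "".join(out)


# ---------------------------------------------------------------------- #
# column classification and block detection


def classify_columns(
    records: Mapping[str, str] | BlockedMSA, lenient: bool = False
) -> list[str]:
    """Label every column ``aligned``, ``unaligned`` or ``spacer``.

    A column is a spacer iff it is all gaps, aligned iff it contains at
    least one upper-case letter and no lower-case one, unaligned in the
    converse case. Mixed-case columns are format errors (majority vote with
    a warning under ``lenient``).
    """
    if isinstance(records, BlockedMSA):
        records = records.records
    rows = list(records.values())
    n_col = len(rows[0])
    classes: list[str] = []
    for c in range(n_col):
        n_upper = n_lower = 0
        for row in rows:
            ch = row[c]
            if ch == GAP:
                continue
            if ch.isupper():
                n_upper += 1
            else:
                n_lower += 1
        if n_upper and n_lower:
            if not lenient:
                raise BlockedMSAFormatError(
                    f"column {c + 1} mixes upper- and lower-case characters"
                )
            warnings.warn(
                f"column {c + 1} mixes cases; classifying by majority",
                stacklevel=2,
            )
            classes.append(ALIGNED if n_upper >= n_lower else UNALIGNED)
        elif n_upper:
            classes.append(ALIGNED)
        elif n_lower:
            classes.append(UNALIGNED)
        else:
            classes.append(SPACER)
    return classes


def detect_blocks(
    classes: Sequence[str], names: Sequence[str] | None = None
) -> BlockLayout:
    """Group classified columns into maximal runs and name them.

    Aligned blocks take the supplied ``names`` in order (count must match)
    or are auto-named A1, A2, ...; unaligned regions are named
    ``"<left>~<right>"`` after their flanking aligned blocks (``NT``/``CT``
    at the alignment ends); spacers are named ``"."``.
    """
    runs: list[tuple[str, int, int]] = []  # (kind, start, end) 1-based
    for i, kind in enumerate(classes):
        if runs and runs[-1][0] == kind:
            runs[-1] = (kind, runs[-1][1], i + 1)
        else:
            runs.append((kind, i + 1, i + 1))

    n_aligned = sum(1 for k, _, _ in runs if k == ALIGNED)
    if names is not None and len(names) != n_aligned:
        raise ValueError(
            f"{len(names)} block names supplied for {n_aligned} aligned blocks"
        )

    aligned_names: list[str] = (
        list(names) if names is not None else [f"A{i + 1}" for i in range(n_aligned)]
    )
    # first pass: assign aligned names
    blocks: list[Block] = []
    a_idx = 0
    for kind, start, end in runs:
        if kind == ALIGNED:
            blocks.append(Block(aligned_names[a_idx], ALIGNED, start, end))
            a_idx += 1
        else:
            blocks.append(Block("", kind, start, end))
    # second pass: name unaligned regions after flanking aligned blocks
    named: list[Block] = []
    for i, b in enumerate(blocks):
        if b.kind != UNALIGNED:
            named.append(b if b.kind == ALIGNED else Block(".", SPACER, b.start, b.end))
            continue
        left = next(
            (x.name for x in reversed(blocks[:i]) if x.kind == ALIGNED), "NT"
        )
        right = next((x.name for x in blocks[i + 1 :] if x.kind == ALIGNED), "CT")
        named.append(Block(f"{left}~{right}", UNALIGNED, b.start, b.end))
    return BlockLayout(tuple(named))


# ---------------------------------------------------------------------- #
# coordinate maps


@dataclass(frozen=True)
class ColumnResidueMap:
    """Bidirectional column <-> residue-number map for one MSA row.

    Residue numbers count non-gap characters 1..L, shifted by (start - 1)
    when the row has a domain start in the metadata. Gap columns map to
    ``None``.
    """

    seqid: str
    start: int
    col_to_res: tuple[int | None, ...]  # index 0-based column -> residue number
    res_to_col: Mapping[int, int] = field(repr=False)  # residue number -> 1-based col

    def residue_at(self, column: int) -> int | None:
        """Residue number at a 1-based column, or None for a gap."""
        return self.col_to_res[column - 1]

    def column_of(self, residue: int) -> int:
        """1-based column holding a residue number."""
        return self.res_to_col[residue]


def column_to_residue(msa: BlockedMSA, seqid: str) -> ColumnResidueMap:
    """Build the column/residue coordinate map for one row."""
    if seqid not in msa.records:
        raise KeyError(f"unknown sequence id {seqid!r}")
    start = msa.start_of(seqid)
    col_to_res: list[int | None] = []
    res_to_col: dict[int, int] = {}
    r = start - 1
    for c, ch in enumerate(msa.records[seqid]):
        if ch == GAP:
            col_to_res.append(None)
        else:
            r += 1
            col_to_res.append(r)
            res_to_col[r] = c + 1
    return ColumnResidueMap(seqid, start, tuple(col_to_res), res_to_col)


# ---------------------------------------------------------------------- #
# extraction and statistics


def extract_aligned_columns(msa: BlockedMSA) -> dict[str, str]:
    """Concatenate the aligned-block columns only (order preserved).

    Returns a plain upper-case MSA: spacer and unaligned columns are
    removed; width equals the sum of aligned-block lengths.
    """
    cols: list[int] = []
    for b in msa.layout.aligned:
        cols.extend(b.columns())
    return {
        sid: "".join(row[c] for c in cols).upper() for sid, row in msa.records.items()
    }


@dataclass(frozen=True)
class BlockTable:
    """Descriptive statistics of a blocked MSA relative to a reference row.

    ``aligned`` has one row per aligned block (name, column range, length,
    reference residue range); ``unaligned`` has one row per unaligned region
    (name, column range, median and maximum insertion length over *all*
    sequences counting zero-length insertions, and the sequence attaining
    the maximum).
    """

    reference_id: str
    aligned: pd.DataFrame
    unaligned: pd.DataFrame

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.aligned.to_csv(buf, sep="\t", index=False)
        buf.write("\n")
        self.unaligned.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def block_statistics(msa: BlockedMSA, reference_id: str) -> BlockTable:
    """Per-block lengths, reference residue ranges and insertion statistics."""
    if reference_id not in msa.records:
        raise KeyError(f"reference id {reference_id!r} not in MSA")
    cmap = column_to_residue(msa, reference_id)

    aligned_rows = []
    for b in msa.layout.aligned:
        residues = [cmap.col_to_res[c] for c in b.columns() if cmap.col_to_res[c]]
        aligned_rows.append(
            {
                "block": b.name,
                "col_start": b.start,
                "col_end": b.end,
                "length": b.length,
                "ref_res_start": residues[0] if residues else None,
                "ref_res_end": residues[-1] if residues else None,
            }
        )

    unaligned_rows = []
    for b in msa.layout.unaligned:
        lengths = {
            sid: sum(1 for c in b.columns() if row[c] != GAP)
            for sid, row in msa.records.items()
        }
        series = pd.Series(lengths)
        argmax_id = series.idxmax()
        unaligned_rows.append(
            {
                "region": b.name,
                "col_start": b.start,
                "col_end": b.end,
                "median_length": float(series.median()),
                "max_length": int(series.max()),
                "longest_in": argmax_id,
            }
        )

    return BlockTable(
        reference_id,
        pd.DataFrame(
            aligned_rows,
            columns=[
                "block",
                "col_start",
                "col_end",
                "length",
                "ref_res_start",
                "ref_res_end",
            ],
        ),
        pd.DataFrame(
            unaligned_rows,
            columns=[
                "region",
                "col_start",
                "col_end",
                "median_length",
                "max_length",
                "longest_in",
            ],
        ),
    )


# ---------------------------------------------------------------------- #
# metadata sidecar


def read_metadata_tsv(text: str) -> pd.DataFrame:
    """Read the sidecar metadata table (id, group, gene, start, end, accession)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("metadata table must have an 'id' column")
    return df.set_index("id")


def read_block_names(text: str) -> list[str]:
    """Read a block-name list: one name per line, '#' comments allowed."""
    names = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line.split()[0])
    return names
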