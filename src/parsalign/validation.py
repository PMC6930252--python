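"""Structural validation of a blocked MSA against pairwise structure alignments.

For each pair of sequences present in both the MSA and a structure-derived
benchmark alignment, three accuracy statistics are computed from the aligned
residue-pair sets:

* **TPR** = N_correct / N_struct — the fraction of structure-aligned residue
  pairs recovered by the MSA (the "developer" score f_D). Structure pairs are
  *skipped* when either residue lies in a lower-case (unaligned) region of
  the MSA: for those residues the MSA makes no homology claim.
* **PPV** = N_correct / N_seq — the fraction of MSA-aligned pairs confirmed
  by the structure alignment (the "modeler" score f_M). MSA pairs are
  *skipped* when either residue is aligned to a gap in the structure
  alignment or absent from it altogether (disordered, no coordinates).
* **Jaccard** = N_correct / N_union with N_union = N_struct + N_seq −
  N_correct, over the retained pairs of either set; it penalises both over-
  and under-alignment.

The module also provides the alignment "gappiness" (mean number of maximal
gap runs per sequence) and the per-reference-residue discrepancy profile.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .blockmsa import GAP, BlockedMSA, column_to_residue
from .pairdata import PairwiseAlignment, ResiduePairSet, induced_pair_set


@dataclass(frozen=True)
class PairScores:
    """Validation counts and rates for one sequence pair.

    Rates are ``None`` when their denominator is zero (no retained pairs).
    """

    id_a: str
    id_b: str
    n_correct: int
    n_struct: int
    n_seq: int

    @property
    def n_union(self) -> int:
        return self.n_struct + self.n_seq - self.n_correct

    @property
    def tpr(self) -> float | None:
        return self.n_correct / self.n_struct if self.n_struct else None

    @property
    def ppv(self) -> float | None:
        return self.n_correct / self.n_seq if self.n_seq else None

    @property
    def jaccard(self) -> float | None:
        return self.n_correct / self.n_union if self.n_union else None


def retained_struct_pairs(
    msa_pairs: ResiduePairSet, struct: PairwiseAlignment
) -> frozenset[tuple[int, int]]:
    """Structure pairs kept for the TPR denominator.

    A structure pair is skipped iff either residue lies in an unaligned
    (lower-case) region of the sequence alignment.
    """
    return frozenset(
        (a, b)
        for a, b in struct.pairs
        if a not in msa_pairs.lower_a and b not in msa_pairs.lower_b
    )


def retained_seq_pairs(
    msa_pairs: ResiduePairSet, struct: PairwiseAlignment
) -> frozenset[tuple[int, int]]:
    """MSA pairs kept for the PPV denominator.

    An MSA pair is skipped iff either residue is aligned to a gap in the
    structure alignment, or absent from it (disordered residues are treated
    as gap-aligned).
    """

    def bad_a(a: int) -> bool:
        return a not in struct.covered_a or a in struct.gap_opposed_a

    def bad_b(b: int) -> bool:
        return b not in struct.covered_b or b in struct.gap_opposed_b

    return frozenset(
        (a, b) for a, b in msa_pairs.pairs if not bad_a(a) and not bad_b(b)
    )


def pair_scores(msa_pairs: ResiduePairSet, struct: PairwiseAlignment) -> PairScores:
    """TPR/PPV/Jaccard counts for one sequence pair.

    Both inputs must refer to the same ordered (id_a, id_b); a transposed
    structure alignment is accepted and flipped.
    """
    if (struct.id_a, struct.id_b) == (msa_pairs.id_b, msa_pairs.id_a):
        struct = struct.transpose()
    if (struct.id_a, struct.id_b) != (msa_pairs.id_a, msa_pairs.id_b):
        raise ValueError(
            f"id mismatch: MSA pair ({msa_pairs.id_a}, {msa_pairs.id_b}) vs "
            f"structure pair ({struct.id_a}, {struct.id_b})"
        )
    n_struct_set = retained_struct_pairs(msa_pairs, struct)
    n_seq_set = retained_seq_pairs(msa_pairs, struct)
    n_correct = len(n_struct_set & n_seq_set)
    return PairScores(
        msa_pairs.id_a, msa_pairs.id_b, n_correct, len(n_struct_set), len(n_seq_set)
    )


# ---------------------------------------------------------------------- #
# whole-MSA validation


@dataclass(frozen=True)
class ValidationReport:
    """Per-pair scores plus aggregate means.

    Aggregate TPR/PPV/Jaccard are unweighted means of the per-pair rates
    over pairs with a defined (nonzero) denominator; ``aggregation`` may be
    ``"pooled"`` instead, in which case counts are summed before dividing.
    ``skipped`` maps skip reasons to counts of affected structure
    alignments.
    """

    per_pair: pd.DataFrame
    mean_tpr: float
    mean_ppv: float
    mean_jaccard: float
    gappiness: float
    aggregation: str
    skipped: Mapping[str, int]

    def summary(self) -> dict:
        return {
            "n_pairs": int(len(self.per_pair)),
            "mean_tpr": self.mean_tpr,
            "mean_ppv": self.mean_ppv,
            "mean_jaccard": self.mean_jaccard,
            "gappiness": self.gappiness,
            "aggregation": self.aggregation,
            "skipped": dict(self.skipped),
        }

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.per_pair.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def validate_msa(
    msa: BlockedMSA,
    struct_alignments: Iterable[PairwiseAlignment],
    id_map: Mapping[str, str] | None = None,
    aggregation: str = "mean",
) -> ValidationReport:
    """Score an MSA against a set of pairwise structure alignments.

    ``id_map`` translates structure-alignment ids to MSA row ids. Structure
    alignments whose ids cannot be mapped are skipped with a warning and
    tallied in the report. Aggregates are unweighted per-pair means by
    default (``aggregation="pooled"`` sums counts first); pairs with a zero
    denominator are excluded from the corresponding mean and tallied.
    """
    if aggregation not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    id_map = dict(id_map or {})
    rows = []
    skipped = {"unmappable_id": 0, "zero_n_struct": 0, "zero_n_seq": 0}
    for aln in struct_alignments:
        map_a = id_map.get(aln.id_a, aln.id_a)
        map_b = id_map.get(aln.id_b, aln.id_b)
        if map_a not in msa.records or map_b not in msa.records:
            warnings.warn(
                f"structure alignment ({aln.id_a}, {aln.id_b}) has no MSA row; skipped",
                stacklevel=2,
            )
            skipped["unmappable_id"] += 1
            continue
        msa_pairs = induced_pair_set(msa, map_a, map_b)
        if (map_a, map_b) != (aln.id_a, aln.id_b):
            aln = PairwiseAlignment(
                map_a,
                map_b,
                aln.pairs,
                aln.covered_a,
                aln.covered_b,
                aln.lower_a,
                aln.lower_b,
                aln.gap_opposed_a,
                aln.gap_opposed_b,
            )
        s = pair_scores(msa_pairs, aln)
        if s.n_struct == 0:
            skipped["zero_n_struct"] += 1
        if s.n_seq == 0:
            skipped["zero_n_seq"] += 1
        rows.append(
            {
                "id_a": s.id_a,
                "id_b": s.id_b,
                "n_correct": s.n_correct,
                "n_struct": s.n_struct,
                "n_seq": s.n_seq,
                "n_union": s.n_union,
                "tpr": s.tpr,
                "ppv": s.ppv,
                "jaccard": s.jaccard,
            }
        )
    per_pair = pd.DataFrame(
        rows,
        columns=[
            "id_a",
            "id_b",
            "n_correct",
            "n_struct",
            "n_seq",
            "n_union",
            "tpr",
            "ppv",
            "jaccard",
        ],
    )
    if aggregation == "mean":
        mean_tpr = float(per_pair["tpr"].dropna().mean()) if len(per_pair) else float("nan")
        mean_ppv = float(per_pair["ppv"].dropna().mean()) if len(per_pair) else float("nan")
        mean_jac = (
            float(per_pair["jaccard"].dropna().mean()) if len(per_pair) else float("nan")
        )
    else:
        nc = per_pair["n_correct"].sum()
        mean_tpr = float(nc / per_pair["n_struct"].sum()) if len(per_pair) else float("nan")
        mean_ppv = float(nc / per_pair["n_seq"].sum()) if len(per_pair) else float("nan")
        mean_jac = float(nc / per_pair["n_union"].sum()) if len(per_pair) else float("nan")
    _, gap_mean = gappiness(msa.records)
    return ValidationReport(
        per_pair, mean_tpr, mean_ppv, mean_jac, gap_mean, aggregation, skipped
    )


# ---------------------------------------------------------------------- #
# gappiness


def gappiness(
    records: Mapping[str, str] | BlockedMSA, internal_only: bool = False
) -> tuple[pd.Series, float]:
    """Count maximal gap runs per sequence and their mean.

    A gap segment is a maximal run of gap characters in one row (case is
    ignored). With ``internal_only`` the leading and trailing runs are
    excluded. Raises on ragged input.
    """
    if isinstance(records, BlockedMSA):
        records = records.records
    lengths = {len(r) for r in records.values()}
    if len(lengths) > 1:
        raise ValueError("gappiness requires an aligned (equal-length) input")
    counts = {}
    for sid, row in records.items():
        segments = [seg for seg in _gap_runs(row)]
        if internal_only:
            n = len(row)
            segments = [(s, e) for s, e in segments if s > 0 and e < n]
        counts[sid] = len(segments)
    series = pd.Series(counts, dtype=int)
    return series, float(series.mean())


def _gap_runs(row: str) -> Iterable[tuple[int, int]]:
    """Yield (start, end) 0-based half-open spans of maximal gap runs."""
    start = None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            yield (start, i)
            start = None
    if start is not None:
        yield (start, len(row))


# ---------------------------------------------------------------------- #
# discrepancy profile


def discrepancy_profile(
    msa: BlockedMSA,
    struct_alignments: Iterable[PairwiseAlignment],
    reference_id: str,
    count_both: bool = False,
) -> tuple[pd.Series, int]:
    """Where the structure benchmark and the MSA disagree, per reference residue.

    Every retained structure pair (TPR skip rule applied) absent from the
    MSA's induced pairs increments the count at the reference residue that
    occupies the MSA column of the pair's first-sequence residue (with
    ``count_both``, the second-sequence residue's column as well). Pairs
    whose column holds a gap in the reference row accumulate in the returned
    ``unmapped`` count.

    Returns a Series indexed by reference residue number (the full domain
    range of the reference row) and the unmapped tally.
    """
    if reference_id not in msa.records:
        raise KeyError(f"reference id {reference_id!r} not in MSA")
    ref_map = column_to_residue(msa, reference_id)
    ref_residues = [r for r in ref_map.col_to_res if r is not None]
    counts = pd.Series(0, index=ref_residues, dtype=int)
    unmapped = 0

    # column lookup per MSA row, built lazily
    res2col_cache: dict[str, Mapping[int, int]] = {}

    def col_of(sid: str, residue: int) -> int | None:
        if sid not in res2col_cache:
            res2col_cache[sid] = column_to_residue(msa, sid).res_to_col
        return res2col_cache[sid].get(residue)

    for aln in struct_alignments:
        if aln.id_a not in msa.records or aln.id_b not in msa.records:
            continue
        msa_pairs = induced_pair_set(msa, aln.id_a, aln.id_b)
        retained = retained_struct_pairs(msa_pairs, aln)
        for a, b in retained - msa_pairs.pairs:
            anchors = [(aln.id_a, a)]
            if count_both:
                anchors.append((aln.id_b, b))
            for sid, residue in anchors:
                col = col_of(sid, residue)
                ref_res = ref_map.residue_at(col) if col is not None else None
                if ref_res is None:
                    unmapped += 1
                else:
                    counts.loc[ref_res] += 1
    return counts, unmapped
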