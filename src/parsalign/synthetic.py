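"""Seeded generator of blocked protein families with known ground truth.

The generator emulates the statistical shape of a blocked kinase-style
alignment: a root consensus of conserved aligned blocks, per-group
divergence, per-sequence substitution noise, and lineage-specific insertions
of geometrically distributed length in the unaligned regions (emitted
lower-case, left-justified). Because the family is built column-first, the
exact residue-pair set of every sequence pair is known, and perturbed
"structure alignments" can be derived from it with a bookkeeping ledger:

* *disorder*: each residue is dropped from a structure alignment with a
  fixed probability (no coordinates); its partner becomes gap-aligned;
* *shift*: with a fixed per-block probability, a run of aligned pairs is
  displaced by one position (a locally shifted secondary-structure
  element), removing whichever pairs the shift invalidates.

The ledger records every dropped and shifted pair, so expected validation
statistics are computable in closed form and compared against the real
pipeline.

Default parameters mimic the kinase study family: 17 aligned blocks with
the deposited block lengths, insertion-length means equal to the deposited
per-region medians, and group/within-group divergences that keep groups
recoverable but non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .blockmsa import GAP, BlockedMSA
from .groupprofile import AMINO_ACIDS, ROBINSON_BACKGROUND
from .pairdata import PairwiseAlignment, ResiduePairSet

#: aligned-block lengths of the deposited kinase alignment (B1N ... HI)
KINASE_BLOCK_LENGTHS = (4, 7, 9, 11, 14, 16, 10, 9, 25, 16, 21, 17, 22, 6, 13, 20, 10)
#: per-region median insertion lengths of the deposited kinase alignment
KINASE_INSERTION_MEANS = (0, 0, 2, 7, 0, 0, 0, 2, 0, 0, 1, 0, 0, 0, 11, 0)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic blocked family.

    Rates are probabilities in [0, 1]; insertion lengths are geometric with
    the given means (zero-length insertions allowed); generation is fully
    reproducible from ``seed``.
    """

    n_groups: int = 4
    seqs_per_group: int = 25
    block_lengths: tuple[int, ...] = KINASE_BLOCK_LENGTHS
    insertion_means: tuple[float, ...] = KINASE_INSERTION_MEANS
    group_divergence: float = 0.4
    within_divergence: float = 0.1
    disorder_rate: float = 0.05
    shift_rate: float = 0.1
    substitution_model: str = "uniform"  # or "background" (Robinson frequencies)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.seqs_per_group < 1:
            raise ValueError("need at least one group and one sequence per group")
        if len(self.insertion_means) != len(self.block_lengths) - 1:
            raise ValueError(
                "need exactly one insertion mean per gap between aligned blocks"
            )
        for rate in (
            self.group_divergence,
            self.within_divergence,
            self.disorder_rate,
            self.shift_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(l < 0 for l in self.block_lengths) or any(
            m < 0 for m in self.insertion_means
        ):
            raise ValueError("lengths must be >= 0")


@dataclass(frozen=True)
class FamilySample:
    """A generated family with its ground truth."""

    spec: FamilySpec
    msa: BlockedMSA
    sequences: dict[str, str]  # plain upper-case, ungapped
    labels: dict[str, str]
    #: per sequence, per aligned block: residue index offset before the block
    block_offsets: dict[str, tuple[int, ...]]
    insertion_lengths: dict[str, tuple[int, ...]]

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def pair_ids(self) -> list[tuple[str, str]]:
        ids = self.ids
        return [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]

    def lower_residues(self, sid: str) -> frozenset[int]:
        """Residue indices lying in unaligned regions (insertions)."""
        out = set()
        offs = self.block_offsets[sid]
        lens = self.spec.block_lengths
        ins = self.insertion_lengths[sid]
        for k in range(len(ins)):
            start = offs[k] + lens[k]  # residues counted before insertion k
            out.update(range(start + 1, start + 1 + ins[k]))
        return frozenset(out)

    def true_pair_set(self, id_a: str, id_b: str) -> ResiduePairSet:
        """The exact residue pairs the generator aligned between two rows."""
        pairs = set()
        for k, length in enumerate(self.spec.block_lengths):
            oa = self.block_offsets[id_a][k]
            ob = self.block_offsets[id_b][k]
            pairs.update((oa + t + 1, ob + t + 1) for t in range(length))
        return ResiduePairSet(
            id_a,
            id_b,
            frozenset(pairs),
            self.lower_residues(id_a),
            self.lower_residues(id_b),
        )


def _mutate(seq: str, rate: float, rng: np.random.Generator, letters: str) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            alt = letters[rng.integers(len(letters))]
            while alt == ch:
                alt = letters[rng.integers(len(letters))]
            out.append(alt)
        else:
            out.append(ch)
    return "".join(out)


def generate_blocked_family(spec: FamilySpec) -> FamilySample:
    """Generate a blocked family and its ground truth from a spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.substitution_model == "uniform":
        letters = AMINO_ACIDS
        probs = None
    elif spec.substitution_model == "background":
        letters = AMINO_ACIDS
        probs = np.array([ROBINSON_BACKGROUND[aa] for aa in AMINO_ACIDS])
        probs = probs / probs.sum()
    else:
        raise ValueError(f"unknown substitution model {spec.substitution_model!r}")

    def draw(n: int) -> str:
        idx = rng.choice(len(letters), size=n, p=probs)
        return "".join(letters[i] for i in idx)

    root = [draw(length) for length in spec.block_lengths]
    group_names = [f"G{g + 1}" for g in range(spec.n_groups)]
    group_consensus = {
        g: [_mutate(block, spec.group_divergence, rng, letters) for block in root]
        for g in group_names
    }

    ids: list[str] = []
    labels: dict[str, str] = {}
    blocks_of: dict[str, list[str]] = {}
    inserts_of: dict[str, list[str]] = {}
    for g in group_names:
        for i in range(spec.seqs_per_group):
            sid = f"{g}_seq{i + 1:03d}"
            ids.append(sid)
            labels[sid] = g
            blocks_of[sid] = [
                _mutate(block, spec.within_divergence, rng, letters)
                for block in group_consensus[g]
            ]
            inserts = []
            for mean in spec.insertion_means:
                if mean <= 0:
                    length = 0
                else:
                    length = int(rng.geometric(1.0 / (1.0 + mean))) - 1
                inserts.append(draw(length).lower())
            inserts_of[sid] = inserts

    region_widths = [
        max(len(inserts_of[sid][k]) for sid in ids)
        for k in range(len(spec.insertion_means))
    ]

    spacer = GAP * 2
    records: dict[str, str] = {}
    for sid in ids:
        parts = [blocks_of[sid][0]]
        for k, width in enumerate(region_widths):
            if width > 0:
                ins = inserts_of[sid][k]
                parts.append(spacer + ins + GAP * (width - len(ins)) + spacer)
            else:
                parts.append(spacer)
            parts.append(blocks_of[sid][k + 1])
        records[sid] = "".join(parts)

    offsets: dict[str, tuple[int, ...]] = {}
    for sid in ids:
        offs, acc = [], 0
        for k, length in enumerate(spec.block_lengths):
            offs.append(acc)
            acc += length
            if k < len(spec.insertion_means):
                acc += len(inserts_of[sid][k])
        offsets[sid] = tuple(offs)

    msa = BlockedMSA(records)
    sequences = {sid: msa.sequence(sid).upper() for sid in ids}
    return FamilySample(
        spec,
        msa,
        sequences,
        labels,
        offsets,
        {sid: tuple(len(s) for s in inserts_of[sid]) for sid in ids},
    )


# ---------------------------------------------------------------------- #
# perturbed structure alignments


@dataclass(frozen=True)
class PerturbationLedger:
    """Exact bookkeeping of the noise applied to one pairwise alignment."""

    id_a: str
    id_b: str
    n_true: int
    dropped_a: frozenset[int]
    dropped_b: frozenset[int]
    shifted: tuple[tuple[int, int, int], ...]  # (a, b_old, b_new)
    removed: tuple[tuple[int, int], ...]  # pairs lost to collisions/overruns


def simulate_structure_alignments(
    sample: FamilySample,
    disorder_rate: float | None = None,
    shift_rate: float | None = None,
    seed: int = 0,
    pair_ids: Sequence[tuple[str, str]] | None = None,
) -> tuple[dict[tuple[str, str], PairwiseAlignment], dict[tuple[str, str], PerturbationLedger]]:
    """Derive noisy structure alignments from the family's true pair sets.

    Rates default to the family spec's. Returns the alignments and the
    per-pair perturbation ledgers; fully reproducible from ``seed``.
    """
    d = sample.spec.disorder_rate if disorder_rate is None else disorder_rate
    s = sample.spec.shift_rate if shift_rate is None else shift_rate
    rng = np.random.default_rng(seed)
    if pair_ids is None:
        pair_ids = sample.pair_ids()

    alignments: dict[tuple[str, str], PairwiseAlignment] = {}
    ledgers: dict[tuple[str, str], PerturbationLedger] = {}
    lengths = {sid: len(seq) for sid, seq in sample.sequences.items()}
    for id_a, id_b in pair_ids:
        la, lb = lengths[id_a], lengths[id_b]
        lower_a = set(sample.lower_residues(id_a))
        lower_b = set(sample.lower_residues(id_b))
        # true pairs grouped by aligned block, in block order
        block_pairs: list[list[tuple[int, int]]] = []
        for k, length in enumerate(sample.spec.block_lengths):
            oa = sample.block_offsets[id_a][k]
            ob = sample.block_offsets[id_b][k]
            block_pairs.append([(oa + t + 1, ob + t + 1) for t in range(length)])
        n_true = sum(len(bp) for bp in block_pairs)

        pairs: dict[int, int] = {}  # a -> b after shifts
        shifted: list[tuple[int, int, int]] = []
        removed: list[tuple[int, int]] = []
        new_pairs: list[tuple[int, int, int]] = []  # (a, b_old, b_new)
        for bp in block_pairs:
            if len(bp) >= 2 and s > 0 and rng.random() < s:
                sign = 1 if rng.random() < 0.5 else -1
                u = int(rng.integers(0, len(bp)))
                m = int(rng.integers(1, len(bp) - u + 1))
                run = set(range(u, u + m))
            else:
                sign = 0
                run = set()
            new_pairs.extend(
                (a, b, b + sign if t in run else b) for t, (a, b) in enumerate(bp)
            )
        # resolve validity and collisions (shifted pairs win over unshifted),
        # globally: a shift at a block edge can land on a neighbouring block
        b_taken: dict[int, tuple[int, int]] = {}  # b_new -> (a, b_old)
        for a, b_old, b_new in new_pairs:
            if b_new < 1 or b_new > lb:
                removed.append((a, b_old))
                continue
            if b_new in b_taken:
                prev_a, prev_b_old = b_taken[b_new]
                if b_new != b_old and b_new == prev_b_old:
                    removed.append((prev_a, prev_b_old))  # unshifted loses
                    b_taken[b_new] = (a, b_old)
                else:
                    removed.append((a, b_old))
            else:
                b_taken[b_new] = (a, b_old)
        for b_new, (a, b_old) in b_taken.items():
            pairs[a] = b_new
            if b_new != b_old:
                shifted.append((a, b_old, b_new))

        # disorder: drop residues independently
        dropped_a = frozenset(r for r in range(1, la + 1) if rng.random() < d)
        dropped_b = frozenset(r for r in range(1, lb + 1) if rng.random() < d)

        covered_a = set(range(1, la + 1)) - dropped_a
        covered_b = set(range(1, lb + 1)) - dropped_b
        final_pairs = set()
        gap_opposed_a, gap_opposed_b = set(), set()
        matched_b = set(pairs.values())
        for a, b in pairs.items():
            if a in dropped_a and b in dropped_b:
                continue
            if a in dropped_a:
                gap_opposed_b.add(b)
            elif b in dropped_b:
                gap_opposed_a.add(a)
            else:
                final_pairs.add((a, b))
        # residues that lost their partner to a shift/collision face a gap
        for a, b in removed:
            if a in covered_a and a not in pairs:
                gap_opposed_a.add(a)
        shifted_b_old = {b_old for _, b_old, _ in shifted}
        for b_old in shifted_b_old:
            if b_old in covered_b and b_old not in matched_b:
                gap_opposed_b.add(b_old)
        # a shifted pair's new B residue is treated as aligned (not lower)
        lower_a -= {a for a, _ in final_pairs} | dropped_a
        lower_b -= {b for _, b in final_pairs} | dropped_b

        key = (id_a, id_b)
        alignments[key] = PairwiseAlignment(
            id_a,
            id_b,
            frozenset(final_pairs),
            frozenset(covered_a),
            frozenset(covered_b),
            frozenset(lower_a),
            frozenset(lower_b),
            frozenset(gap_opposed_a),
            frozenset(gap_opposed_b),
        )
        ledgers[key] = PerturbationLedger(
            id_a,
            id_b,
            n_true,
            dropped_a,
            dropped_b,
            tuple(sorted(shifted)),
            tuple(sorted(removed)),
        )
    return alignments, ledgers


def expected_pair_metrics(
    sample: FamilySample,
    aln: PairwiseAlignment,
    ledger: PerturbationLedger,
) -> tuple[float | None, float | None, float | None]:
    """Closed-form (TPR, PPV, Jaccard) for one perturbed pair from the ledger.

    Derived purely from the generator's bookkeeping: the true pair set, the
    dropped/shifted records and the MSA's unaligned-region membership —
    not from the MSA-induction + scoring pipeline it is used to check.
    """
    truth = sample.true_pair_set(ledger.id_a, ledger.id_b)
    low_a, low_b = truth.lower_a, truth.lower_b

    correct = {
        (a, b)
        for a, b in truth.pairs & aln.pairs  # surviving, unshifted
    }
    # TPR denominator: struct pairs not touching MSA-lower residues
    n_struct = sum(
        1 for a, b in aln.pairs if a not in low_a and b not in low_b
    )
    # PPV denominator: true (= MSA) pairs whose residues are present in the
    # structure and not aligned to gaps there
    n_seq = sum(
        1
        for a, b in truth.pairs
        if a in aln.covered_a
        and b in aln.covered_b
        and a not in aln.gap_opposed_a
        and b not in aln.gap_opposed_b
    )
    n_correct = len(correct)
    tpr = n_correct / n_struct if n_struct else None
    ppv = n_correct / n_seq if n_seq else None
    union = n_struct + n_seq - n_correct
    jac = n_correct / union if union else None
    return tpr, ppv, jac


def write_labels_tsv(labels: Mapping[str, str]) -> str:
    lines = ["id\tgroup"]
    lines += [f"{sid}\t{g}" for sid, g in labels.items()]
    return "\n".join(lines) + "\n"


def read_labels_tsv(text: str) -> dict[str, str]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:2] != ["id", "group"]:
        raise ValueError("labels TSV must have header 'id\\tgroup'")
    out = {}
    for ln in lines[1:]:
        sid, g = ln.split("\t")[:2]
        out[sid] = g
    return out
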