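"""Per-group sequence profiles and the two-pass group-reassignment procedure.

Each named group (for kinases: AGC, CAMK, CK1, CMGC, NEK, RGC, STE, TKL,
TYR) gets a position-specific scoring model built from its rows of the main
blocked MSA (empty columns deleted). Match columns are those with at most
50% gaps; per-column amino-acid emissions are pseudocount-smoothed
frequencies and scores are log-odds against a background distribution, in
bits. Sequences are scored by the best *local* alignment of the sequence to
the profile columns under affine gap penalties (Smith-Waterman over match
columns), and each sequence is assigned to the highest-scoring group if that
score clears a threshold; everything else stays in the catch-all OTHER
label. The threshold is recalibrated from the data (the score value
separating within-group from OTHER score distributions) rather than carried
over from any external tool's scale.

The reassignment procedure runs exactly two passes: profiles from the
initial labels, reassignment of passing OTHER sequences, then one rebuild
and rescore with the updated labels.
"""

from __future__ import annotations

import json

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blockmsa import GAP, BlockedMSA

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Robinson-Robinson amino-acid background frequencies (optional alternative
#: to the uniform default), normalised.
ROBINSON_BACKGROUND = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


@dataclass(frozen=True)
class GroupProfile:
    """A per-column log-odds model for one group.

    ``log_odds`` is (n_columns, 20) in bits; ``probs`` the smoothed emission
    probabilities (each row sums to 1). ``gap_open``/``gap_extend`` are
    positive penalties in bits with open >= extend.
    """

    group: str
    log_odds: np.ndarray
    probs: np.ndarray
    background: np.ndarray
    gap_open: float
    gap_extend: float
    n_sequences: int
    pseudocount: float

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("emission probabilities must sum to 1 per column")
        if not np.isfinite(self.log_odds).all():
            raise ValueError("log-odds scores must be finite")

    @property
    def n_columns(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "group": self.group,
                "log_odds": self.log_odds.tolist(),
                "probs": self.probs.tolist(),
                "background": self.background.tolist(),
                "gap_open": self.gap_open,
                "gap_extend": self.gap_extend,
                "n_sequences": self.n_sequences,
                "pseudocount": self.pseudocount,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroupProfile":
        d = json.loads(text)
        return cls(
            d["group"],
            np.asarray(d["log_odds"], dtype=float),
            np.asarray(d["probs"], dtype=float),
            np.asarray(d["background"], dtype=float),
            d["gap_open"],
            d["gap_extend"],
            d["n_sequences"],
            d["pseudocount"],
        )


# ---------------------------------------------------------------------- #
# sub-MSA helpers


def delete_empty_columns(records: Mapping[str, str]) -> dict[str, str]:
    """Drop columns that are gaps in every sequence."""
    rows = list(records.values())
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    return {sid: "".join(row[c] for c in keep) for sid, row in records.items()}


def group_submsa(msa: BlockedMSA, ids: Iterable[str]) -> dict[str, str]:
    """Extract the rows of one group from a blocked MSA and delete empty
    columns (upper-cased: case semantics are not used by profiles)."""
    sub = {sid: msa.records[sid].upper() for sid in ids}
    if not sub:
        raise ValueError("empty group: no sequences")
    return delete_empty_columns(sub)


# ---------------------------------------------------------------------- #
# profile construction


def build_group_profile(
    sub_records: Mapping[str, str],
    group: str = "",
    pseudocount: float = 1.0,
    background: Mapping[str, float] | None = None,
    max_gap_fraction: float = 0.5,
    gap_open: float = 4.0,
    gap_extend: float = 0.5,
) -> GroupProfile:
    """Build a log-odds profile from a group sub-alignment.

    Match columns are those with gap fraction <= ``max_gap_fraction``; other
    columns are dropped. Per-column emissions are
    ``(counts + pseudocount * background) / (n_residues + pseudocount)``;
    scores are log2(emission / background) bits. 'X' and other ambiguity
    codes are excluded from the counts.
    """
    if not sub_records:
        raise ValueError("cannot build a profile from an empty sub-MSA")
    rows = [r.upper() for r in sub_records.values()]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("sub-MSA rows differ in length")
    n_seq = len(rows)
    if background is None:
        q = np.full(20, 1.0 / 20)
    else:
        q = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
        q = q / q.sum()

    probs_rows, lods_rows = [], []
    for c in range(len(rows[0])):
        column = [r[c] for r in rows]
        n_gap = sum(1 for ch in column if ch == GAP)
        if n_gap / n_seq > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for ch in column:
            i = _AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
        n_res = counts.sum()
        p = (counts + pseudocount * q) / (n_res + pseudocount)
        probs_rows.append(p)
        lods_rows.append(np.log2(p / q))
    if not probs_rows:
        raise ValueError("no match columns survive the gap-fraction rule")
    return GroupProfile(
        group,
        np.array(lods_rows),
        np.array(probs_rows),
        q,
        gap_open,
        gap_extend,
        n_seq,
        pseudocount,
    )


# ---------------------------------------------------------------------- #
# scoring


def score_sequence(profile: GroupProfile, sequence: str) -> float:
    """Best local alignment score of a sequence to the profile, in bits.

    Smith-Waterman over the profile's match columns with affine gap
    penalties; deterministic; an empty sequence scores 0. Residues outside
    the 20-letter alphabet score 0 (background-neutral) at every column.
    """
    seq = [c for c in sequence.upper() if c != GAP]
    if not seq:
        return 0.0
    m = profile.n_columns
    go, ge = profile.gap_open, profile.gap_extend
    lods = profile.log_odds
    js = np.arange(m)
    neutral = np.zeros(m)

    h_prev = np.zeros(m)
    f_prev = np.full(m, -np.inf)
    best = 0.0
    for ch in seq:
        i = _AA_INDEX.get(ch)
        col_scores = lods[:, i] if i is not None else neutral
        diag = np.concatenate(([0.0], h_prev[:-1])) + col_scores
        f = np.maximum(h_prev - go, f_prev - ge)
        cand = np.maximum.reduce([diag, f, np.zeros(m)])
        # gap along the profile (deletion of profile columns), prefix-scan form:
        # E[j] = max_{k<j} cand[k] - go - (j-1-k) * ge
        t = np.maximum.accumulate(cand + ge * js)
        e = np.concatenate(([-np.inf], t[:-1])) - go - ge * (js - 1)
        h = np.maximum(cand, e)
        best = max(best, float(h.max()))
        h_prev, f_prev = h, f
    return best


@dataclass(frozen=True)
class GroupAssignment:
    """Per-sequence classification result."""

    seqid: str
    scores: Mapping[str, float]
    best: str
    margin: float
    passed: bool

    @property
    def best_score(self) -> float:
        return self.scores[self.best]


def assign_groups(
    profiles: Sequence[GroupProfile],
    sequences: Mapping[str, str],
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score every sequence against every profile and pick the best group.

    Returns a DataFrame indexed by sequence id with one score column per
    group plus ``best``, ``best_score``, ``margin`` (to the runner-up) and
    ``passed`` (best_score >= threshold; all True when no threshold).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 group profiles to assign groups")
    groups = [p.group for p in profiles]
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group names among profiles")
    rows = {}
    for sid, seq in sequences.items():
        rows[sid] = [score_sequence(p, seq) for p in profiles]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=groups)
    order = np.argsort(-df.values, axis=1)
    df["best"] = [groups[i] for i in order[:, 0]]
    df["best_score"] = df[groups].max(axis=1)
    runner = [df.iloc[k, order[k, 1]] for k in range(len(df))]
    df["margin"] = df["best_score"] - np.array(runner, dtype=float)
    df["passed"] = True if threshold is None else df["best_score"] >= threshold
    return df


def calibrate_threshold(
    member_scores: Sequence[float], nonmember_scores: Sequence[float]
) -> float:
    """A score cutoff separating group membership from non-membership.

    Midpoint between the 5th percentile of the labelled members' own-group
    scores and the 95th percentile of the non-member scores (each member's
    best score under the *other* groups' profiles — the natural negative
    class, since unassigned sequences may be unrecognised members). With no
    non-member scores available, half the minimum member score is used.
    """
    member_scores = np.asarray(member_scores, dtype=float)
    if member_scores.size == 0:
        raise ValueError("cannot calibrate a threshold without member scores")
    if len(nonmember_scores) == 0:
        return float(member_scores.min() / 2)
    lo = float(np.percentile(member_scores, 5))
    hi = float(np.percentile(np.asarray(nonmember_scores, dtype=float), 95))
    return (lo + hi) / 2


# ---------------------------------------------------------------------- #
# two-pass reassignment


@dataclass(frozen=True)
class ReassignmentResult:
    labels: dict[str, str]
    assignments: pd.DataFrame  # final-pass score table
    audit: list[dict]
    threshold: float


def iterate_assignment(
    msa: BlockedMSA,
    initial_labels: Mapping[str, str],
    threshold: float | str = "auto",
    other_label: str = "OTHER",
    pseudocount: float = 1.0,
    background: Mapping[str, float] | None = None,
) -> ReassignmentResult:
    """Two-pass profile-based reassignment of unclassified sequences.

    Pass 1 builds one profile per non-OTHER group from the labelled rows of
    the MSA, scores every sequence, and moves OTHER sequences whose best
    score clears the threshold into their best group. Pass 2 rebuilds the
    profiles with the updated labels and rescores; the procedure stops after
    pass 2. The audit log records every label change. ``threshold="auto"``
    recalibrates the cutoff from the pass-1 score distributions.
    """
    labels = {sid: initial_labels[sid] for sid in msa.records}
    audit: list[dict] = []
    thr: float | None = None if threshold == "auto" else float(threshold)
    sequences = {sid: msa.sequence(sid).upper() for sid in msa.records}
    df = None

    for pass_no in (1, 2):
        groups = sorted({g for g in labels.values() if g != other_label})
        if not groups:
            raise ValueError("no labelled groups to build profiles from")
        profiles = []
        for g in groups:
            members = [sid for sid, lab in labels.items() if lab == g]
            if not members:
                raise ValueError(f"group {g!r} lost all members")
            profiles.append(
                build_group_profile(
                    group_submsa(msa, members),
                    group=g,
                    pseudocount=pseudocount,
                    background=background,
                )
            )
        df = assign_groups(profiles, sequences)
        if thr is None:
            member_self, cross_best = [], []
            for sid in df.index:
                lab = labels[sid]
                if lab == other_label:
                    continue
                member_self.append(df.loc[sid, lab])
                cross = [df.loc[sid, g] for g in groups if g != lab]
                if cross:
                    cross_best.append(max(cross))
            thr = calibrate_threshold(member_self, cross_best)
        for sid in df.index:
            if labels[sid] != other_label:
                continue
            if df.loc[sid, "best_score"] >= thr:
                new = df.loc[sid, "best"]
                audit.append(
                    {
                        "pass": pass_no,
                        "id": sid,
                        "from": other_label,
                        "to": new,
                        "score": float(df.loc[sid, "best_score"]),
                    }
                )
                labels[sid] = new
    df = df.copy()
    df["passed"] = df["best_score"] >= thr
    return ReassignmentResult(labels, df, audit, float(thr))
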