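"""Validation statistics: skip rules, aggregation, gappiness, discrepancies."""

import numpy as np
import pytest

from parsalign import (
    PairwiseAlignment,
    ResiduePairSet,
    induced_pair_set,
    pair_scores,
    parse_blocked_msa,
    validate_msa,
)
from parsalign.validation import discrepancy_profile, gappiness

from helpers import (
    oracle_pair_scores,
    random_validation_instance,
    struct_from_induced,
)


def make_struct(pairs, cov_a, cov_b, **kw):
    return PairwiseAlignment(
        "A", "B", frozenset(pairs), frozenset(cov_a), frozenset(cov_b), **kw
    )


class TestPairScores:
    def test_perfect_agreement(self):
        rps = ResiduePairSet("A", "B", frozenset({(1, 1), (2, 2), (3, 3)}))
        struct = make_struct({(1, 1), (2, 2), (3, 3)}, {1, 2, 3}, {1, 2, 3})
        s = pair_scores(rps, struct)
        assert (s.tpr, s.ppv, s.jaccard) == (1.0, 1.0, 1.0)

    def test_tpr_skip_rule_on_lower_case_residue(self):
        # structure aligns (3,3) but residue 3 of A is in an unaligned region
        rps = ResiduePairSet(
            "A", "B", frozenset({(1, 1), (2, 2)}), lower_a=frozenset({3})
        )
        struct = make_struct({(1, 1), (2, 2), (3, 3)}, {1, 2, 3}, {1, 2, 3})
        s = pair_scores(rps, struct)
        assert (s.n_struct, s.n_seq, s.n_correct) == (2, 2, 2)
        assert (s.tpr, s.ppv, s.jaccard) == (1.0, 1.0, 1.0)

    def test_complete_disagreement(self):
        rps = ResiduePairSet("A", "B", frozenset({(1, 2), (2, 3)}))
        struct = make_struct({(1, 1), (2, 2), (3, 3)}, {1, 2, 3}, {1, 2, 3})
        s = pair_scores(rps, struct)
        assert s.n_correct == 0
        assert (s.tpr, s.ppv, s.jaccard) == (0.0, 0.0, 0.0)

    def test_ppv_skip_rule_on_disordered_residue(self):
        # residue 2 of A absent from the structure: MSA pair (2,2) skipped
        rps = ResiduePairSet("A", "B", frozenset({(1, 1), (2, 2)}))
        struct = make_struct({(1, 1)}, {1}, {1, 2})
        s = pair_scores(rps, struct)
        assert (s.n_seq, s.n_struct, s.n_correct) == (1, 1, 1)
        assert s.ppv == 1.0

    def test_ppv_skip_rule_on_gap_aligned_residue(self):
        rps = ResiduePairSet("A", "B", frozenset({(1, 1), (2, 2)}))
        struct = make_struct(
            {(1, 1)}, {1, 2}, {1, 2}, gap_opposed_a=frozenset({2})
        )
        assert pair_scores(rps, struct).n_seq == 1

    def test_id_mismatch(self):
        rps = ResiduePairSet("A", "B", frozenset())
        struct = make_struct(set(), set(), set())
        with pytest.raises(ValueError, match="id mismatch"):
            pair_scores(
                ResiduePairSet("A", "C", frozenset()), struct
            )

    def test_transposed_structure_accepted(self):
        rps = ResiduePairSet("A", "B", frozenset({(1, 2)}))
        struct = PairwiseAlignment(
            "B", "A", frozenset({(2, 1)}), frozenset({1, 2}), frozenset({1})
        )
        assert pair_scores(rps, struct).tpr == 1.0

    def test_undefined_rates_flagged_none(self):
        rps = ResiduePairSet("A", "B", frozenset())
        struct = make_struct(set(), {1}, {1})
        s = pair_scores(rps, struct)
        assert s.tpr is None and s.ppv is None and s.jaccard is None


class TestOracleEquivalence:
    def test_matches_brute_force_on_200_random_instances(self):
        """pair_scores over the full induction pipeline equals a naive
        column-walking oracle on random noisy instances."""
        for seed in range(200):
            sample, aln, _ = random_validation_instance(seed)
            id_a, id_b = sample.ids
            s = pair_scores(induced_pair_set(sample.msa, id_a, id_b), aln)
            row_a = sample.msa.records[id_a]
            row_b = sample.msa.records[id_b]
            expected = oracle_pair_scores(row_a, row_b, aln)
            assert (s.n_correct, s.n_struct, s.n_seq) == expected, seed
            # Jaccard identity on every instance
            assert s.n_union == s.n_struct + s.n_seq - s.n_correct
            if s.n_correct:
                assert s.jaccard == s.n_correct / (s.n_struct + s.n_seq - s.n_correct)

    def test_score_ordering_invariant(self):
        for seed in range(50):
            _, aln, _ = random_validation_instance(seed)
            sample, aln, _ = random_validation_instance(seed)
            s = pair_scores(induced_pair_set(sample.msa, *sample.ids), aln)
            if s.jaccard is not None and s.tpr is not None and s.ppv is not None:
                assert s.jaccard <= min(s.tpr, s.ppv) + 1e-12


class TestMonotonicity:
    def test_adding_correct_pair_never_decreases_tpr(self):
        struct = make_struct({(1, 1), (2, 2), (3, 3)}, {1, 2, 3}, {1, 2, 3})
        base = ResiduePairSet("A", "B", frozenset({(1, 1)}))
        more = ResiduePairSet("A", "B", frozenset({(1, 1), (2, 2)}))
        assert pair_scores(more, struct).tpr >= pair_scores(base, struct).tpr

    def test_adding_incorrect_pair_never_increases_ppv(self):
        struct = make_struct({(1, 1), (2, 2), (3, 3)}, {1, 2, 3}, {1, 2, 3})
        base = ResiduePairSet("A", "B", frozenset({(1, 1)}))
        worse = ResiduePairSet("A", "B", frozenset({(1, 1), (2, 3)}))
        assert pair_scores(worse, struct).ppv <= pair_scores(base, struct).ppv


class TestValidateMSA:
    def test_self_induced_alignments_score_exactly_one(self, small_family):
        msa = small_family.msa
        alns = [
            struct_from_induced(
                induced_pair_set(msa, a, b),
                len(small_family.sequences[a]),
                len(small_family.sequences[b]),
            )
            for a, b in small_family.pair_ids()[:20]
        ]
        report = validate_msa(msa, alns)
        assert report.mean_tpr == 1.0
        assert report.mean_ppv == 1.0
        assert report.mean_jaccard == 1.0

    def test_unmappable_id_skipped_with_warning(self, small_family):
        ghost = make_struct({(1, 1)}, {1}, {1})
        with pytest.warns(UserWarning, match="no MSA row"):
            report = validate_msa(small_family.msa, [ghost])
        assert report.skipped["unmappable_id"] == 1
        assert len(report.per_pair) == 0

    def test_id_map_translation(self, small_family):
        a, b = small_family.ids[:2]
        rps = induced_pair_set(small_family.msa, a, b)
        struct = PairwiseAlignment(
            "pdbA",
            "pdbB",
            rps.pairs,
            frozenset(range(1, len(small_family.sequences[a]) + 1)),
            frozenset(range(1, len(small_family.sequences[b]) + 1)),
            rps.lower_a,
            rps.lower_b,
        )
        report = validate_msa(
            small_family.msa, [struct], id_map={"pdbA": a, "pdbB": b}
        )
        assert report.mean_tpr == 1.0

    def test_pooled_vs_mean_aggregation(self, small_family):
        from parsalign.synthetic import simulate_structure_alignments

        alns, _ = simulate_structure_alignments(
            small_family, disorder_rate=0.1, shift_rate=0.3, seed=9
        )
        mean_rep = validate_msa(small_family.msa, alns.values())
        pooled_rep = validate_msa(
            small_family.msa, alns.values(), aggregation="pooled"
        )
        assert 0 < pooled_rep.mean_tpr < 1
        # both estimates target the same quantity and must agree broadly
        assert abs(mean_rep.mean_tpr - pooled_rep.mean_tpr) < 0.05


class TestGappiness:
    @pytest.mark.parametrize(
        "row,total,internal",
        [
            ("ACDE", 0, 0),
            ("A--CD-E", 2, 2),
            ("--ACDE", 1, 0),
            ("A--CD-E--", 3, 2),
            ("----", 1, 0),
        ],
    )
    def test_gap_segment_counting(self, row, total, internal):
        counts, _ = gappiness({"s": row})
        assert counts["s"] == total
        counts, _ = gappiness({"s": row}, internal_only=True)
        assert counts["s"] == internal

    def test_mean_over_sequences(self):
        _, mean = gappiness({"a": "A-A-A", "b": "AAAAA"})
        assert mean == 1.0

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            gappiness({"a": "AA", "b": "AAA"})


class TestDiscrepancyProfile:
    def test_perfect_agreement_zero_profile(self, toy_msa):
        rps = induced_pair_set(toy_msa, "A", "B")
        struct = struct_from_induced(rps, 6, 5)
        counts, unmapped = discrepancy_profile(toy_msa, [struct], "A")
        assert counts.sum() == 0 and unmapped == 0

    def test_one_misaligned_pair_lands_on_reference_residue(self):
        msa = parse_blocked_msa(">R\nMKVQ\n>B\nMRVQ\n")
        rps = induced_pair_set(msa, "R", "B")
        # structure says (2,3): disagrees with the MSA's (2,2)/(3,3)
        struct = make_struct({(1, 1), (2, 3), (4, 4)}, {1, 2, 3, 4}, {1, 2, 3, 4})
        struct = PairwiseAlignment(
            "R", "B", struct.pairs, struct.covered_a, struct.covered_b
        )
        counts, unmapped = discrepancy_profile(msa, [struct], "R")
        assert counts.loc[2] == 1
        assert counts.drop(2).sum() == 0 and unmapped == 0

    def test_empty_structure_set_zero_profile(self, toy_msa):
        counts, unmapped = discrepancy_profile(toy_msa, [], "A")
        assert counts.sum() == 0 and unmapped == 0

    def test_missing_reference(self, toy_msa):
        with pytest.raises(KeyError):
            discrepancy_profile(toy_msa, [], "nope")
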