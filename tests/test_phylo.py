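"""Phylogeny: p-distance, NJ, bootstrap replicates, TBE, Newick I/O."""

import numpy as np
import pytest

from parsalign import phylo

from helpers import (
    oracle_transfer_distance,
    random_tree,
    tree_patristic_matrix,
)


class TestPDistance:
    def test_identical_sequences(self):
        dm = phylo.p_distance_matrix({"a": "MKVQ", "b": "MKVQ"})
        assert dm[("a", "b")] == 0.0

    def test_simple_proportion(self):
        dm = phylo.p_distance_matrix({"a": "AAAA", "b": "TAAA"})
        assert dm[("a", "b")] == 0.25

    def test_gap_sites_excluded_pairwise(self):
        dm = phylo.p_distance_matrix({"a": "AA-A", "b": "AATA"})
        assert dm[("a", "b")] == 0.0

    def test_x_excluded_and_case_insensitive(self):
        dm = phylo.p_distance_matrix({"a": "aXtt", "b": "AATA"})
        assert dm[("a", "b")] == pytest.approx(1 / 3)

    def test_complete_deletion(self):
        dm = phylo.p_distance_matrix(
            {"a": "AA-A", "b": "ATTA", "c": "ATTA"}, deletion="complete"
        )
        # column 3 removed for everyone: a vs b differ at 1 of 3 sites
        assert dm[("a", "b")] == pytest.approx(1 / 3)

    def test_zero_comparable_sites_flagged(self):
        dm = phylo.p_distance_matrix({"a": "A-", "b": "-A"})
        assert dm.has_undefined

    def test_column_permutation_invariance(self, small_family):
        from parsalign import extract_aligned_columns

        plain = extract_aligned_columns(small_family.msa)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(next(iter(plain.values()))))
        shuffled = {sid: "".join(row[i] for i in perm) for sid, row in plain.items()}
        d1 = phylo.p_distance_matrix(plain)
        d2 = phylo.p_distance_matrix(shuffled)
        assert np.allclose(d1.values, d2.values)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(("A", "B", "C"), d))
        # vA = (dAB + dAC - dBC)/2 etc.
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.3)
        assert lengths["C"] == pytest.approx(0.5)

    def test_equilateral_star(self):
        d = np.full((3, 3), 0.8)
        np.fill_diagonal(d, 0.0)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(("A", "B", "C"), d))
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.4)

    def test_four_equidistant_taxa_zero_internal_branch(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = phylo.neighbor_joining(
            phylo.DistanceMatrix(("A", "B", "C", "D"), d)
        )
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal and all(x == pytest.approx(0.0) for x in internal)

    @pytest.mark.parametrize("n_leaves", [5, 8, 12, 20])
    def test_additive_matrix_recovery(self, n_leaves):
        """NJ is consistent: it reconstructs the generating tree exactly
        (topology and branch lengths) from additive distances."""
        rng = np.random.default_rng(n_leaves)
        for rep in range(5):
            truth = random_tree([f"T{i:02d}" for i in range(n_leaves)], rng)
            ids, d = tree_patristic_matrix(truth)
            scale = 1.0
            if d.max() > 1:
                scale = d.max() * 1.01
                d = d / scale
            nj = phylo.neighbor_joining(phylo.DistanceMatrix(ids, d))
            assert phylo.nontrivial_bipartitions(nj) == phylo.nontrivial_bipartitions(
                truth
            )
            # branch-length recovery via the distance matrix it induces
            _, d_back = tree_patristic_matrix(nj)
            assert np.allclose(d_back, d, atol=1e-9)

    def test_deterministic_output(self, small_family):
        from parsalign import extract_aligned_columns

        plain = extract_aligned_columns(small_family.msa)
        dm = phylo.p_distance_matrix(plain)
        t1 = phylo.write_newick(phylo.neighbor_joining(dm))
        t2 = phylo.write_newick(phylo.neighbor_joining(dm))
        assert t1 == t2

    def test_matches_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        truth = random_tree([f"T{i}" for i in range(9)], rng)
        ids, d = tree_patristic_matrix(truth)
        ours = phylo.neighbor_joining(phylo.DistanceMatrix(ids, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        theirs_dp = phylo.read_newick(str(theirs).strip())
        assert phylo.nontrivial_bipartitions(ours) == phylo.nontrivial_bipartitions(
            theirs_dp
        )

    def test_undefined_distance_rejected(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(ValueError, match="prune or impute"):
            phylo.neighbor_joining(phylo.DistanceMatrix(("A", "B", "C"), d))

    def test_too_few_taxa(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="at least 3"):
            phylo.neighbor_joining(phylo.DistanceMatrix(("A", "B"), d))


class TestBootstrap:
    def test_replicates_preserve_width_and_ids(self):
        records = {"a": "MKVQST", "b": "MRVQST"}
        reps = list(phylo.bootstrap_columns(records, 5, seed=1))
        assert len(reps) == 5
        for rep in reps:
            assert set(rep) == {"a", "b"}
            assert all(len(r) == 6 for r in rep.values())

    def test_same_seed_byte_identical(self):
        records = {"a": "MKVQST", "b": "MRVQST"}
        r1 = list(phylo.bootstrap_columns(records, 4, seed=9))
        r2 = list(phylo.bootstrap_columns(records, 4, seed=9))
        assert r1 == r2

    def test_mean_column_sampling_count(self):
        # one row of 10 distinct letters: occurrences count column samples
        row = "ACDEFGHIKL"
        n_rep = 10_000
        totals = {c: 0 for c in row}
        for rep in phylo.bootstrap_columns({"s": row}, n_rep, seed=3):
            for c in rep["s"]:
                totals[c] += 1
        # each column's count is Binomial(10 * n_rep, 1/10): mean 1 per replicate
        se = np.sqrt(10 * n_rep * 0.1 * 0.9) / n_rep
        for c, total in totals.items():
            assert abs(total / n_rep - 1.0) < 3 * se


class TestTransferSupport:
    def test_identical_replicates_give_full_support(self):
        ref = phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        reps = [phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);") for _ in range(4)]
        phylo.transfer_support(ref, reps)
        assert sorted(phylo.support_by_bipartition(ref).values()) == [100.0, 100.0]

    def test_moved_cherry_contributes_zero(self):
        # cherry {A,B} has p=2; moving B gives delta=1 -> 1 - 1/(p-1) = 0
        ref = phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        reps = [phylo.read_newick("((A:1,E:1):1,(C:1,D:1):1,B:1);")]
        phylo.transfer_support(ref, reps)
        supports = phylo.support_by_bipartition(ref)
        assert sorted(supports.values()) == [0.0, 100.0]

    def test_naive_transfer_distance_equals_brute_force(self):
        rng = np.random.default_rng(11)
        labels = [f"T{i}" for i in range(6)]
        index = {lab: i for i, lab in enumerate(sorted(labels))}
        for _ in range(20):
            ref = random_tree(labels, rng)
            rep = random_tree(labels, rng)
            rep_masks = [m for _, m in phylo._edge_masks(rep, index)]
            for node, mask in phylo._edge_masks(ref, index):
                size = mask.bit_count()
                if not (1 < size < 5):
                    continue
                leafset = frozenset(
                    lab for lab, i in index.items() if mask >> i & 1
                )
                ours = phylo.transfer_distance(mask, rep_masks, 6)
                assert ours == oracle_transfer_distance(leafset, rep)

    def test_tbe_at_least_classical_branchwise(self):
        rng = np.random.default_rng(5)
        labels = [f"T{i}" for i in range(10)]
        ref = random_tree(labels, rng)
        reps = [random_tree(labels, rng) for _ in range(30)]
        phylo.transfer_support(ref, reps)
        tbe = phylo.support_by_bipartition(ref)
        classical = phylo.classical_support(ref, reps)
        assert set(tbe) == set(classical)
        for mask in tbe:
            assert tbe[mask] >= classical[mask] - 1e-9
            assert 0.0 <= tbe[mask] <= 100.0

    def test_leaf_branches_carry_no_support(self):
        ref = phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        phylo.transfer_support(ref, [phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")])
        for leaf in ref.leaf_node_iter():
            assert getattr(leaf, "support", None) is None

    def test_leaf_set_mismatch_rejected(self):
        ref = phylo.read_newick("((A:1,B:1):1,C:1,D:1);")
        bad = phylo.read_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError, match="leaf set"):
            phylo.transfer_support(ref, [bad])


class TestNewick:
    def test_canonical_round_trip_byte_identical(self):
        s = "(A:1,B:2,(C:3,D:4):5);"
        assert phylo.write_newick(phylo.read_newick(s)) == s

    def test_supports_round_trip_as_internal_labels(self):
        s = "(A:1,B:2,(C:3,D:4)87:5);"
        tree = phylo.read_newick(s)
        internal = [n for n in tree.preorder_node_iter() if n.label]
        assert internal[0].support == 87.0
        assert phylo.write_newick(tree) == s

    def test_random_tree_round_trips(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            tree = random_tree([f"T{i}" for i in range(int(rng.integers(4, 10)))], rng)
            text = phylo.write_newick(tree)
            again = phylo.read_newick(text)
            assert phylo.write_newick(again) == text
            assert phylo.nontrivial_bipartitions(again) == phylo.nontrivial_bipartitions(tree)

    def test_malformed_newick_raises(self):
        with pytest.raises(Exception):
            phylo.read_newick("((A,B);")
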