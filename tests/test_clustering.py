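"""Identity clustering, profiles and merge trees."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinfams._align import AMINO_ACIDS, BLOSUM62, encode
from kinfams.clustering import (
    SeqCluster,
    build_merge_tree,
    build_profile,
    greedy_cluster,
    pairwise_identity,
    position_based_weights,
    score_profiles,
)

AA = list(AMINO_ACIDS)
seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40)


def rand_seq(rng, n):
    return "".join(rng.choice(AA, size=n))


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == 1.0

    def test_three_of_four(self):
        assert pairwise_identity("ACDE", "ACDF") == 0.75

    def test_shorter_sequence_denominator(self):
        # 4 matches / min(4, 8)
        assert pairwise_identity("AAAA", "AAAAAAAA") == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    def test_matches_biopython_oracle(self):
        Align = pytest.importorskip("Bio.Align")
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        aligner.mode = "global"
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rand_seq(rng, int(rng.integers(10, 60)))
            b = rand_seq(rng, int(rng.integers(10, 60)))
            aln = aligner.align(a, b)[0]
            ident = sum(
                1 for x, y in zip(*aln) if x == y and x != "-"
            ) / min(len(a), len(b))
            assert pairwise_identity(a, b) == pytest.approx(ident, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq_strategy, seq_strategy)
    def test_symmetric_and_bounded(self, a, b):
        x = pairwise_identity(a, b)
        assert 0.0 <= x <= 1.0
        assert x == pytest.approx(pairwise_identity(b, a))


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        units = [(f"s{i}", "MKTAYIAKQRQISFVK" * 5) for i in range(5)]
        clusters = greedy_cluster(units)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_distant_groups_two_clusters(self):
        rng = np.random.default_rng(0)
        a, b = rand_seq(rng, 80), rand_seq(rng, 80)
        assert pairwise_identity(a, b) < 0.5
        clusters = greedy_cluster([("a1", a), ("a2", a), ("b1", b), ("b2", b)])
        assert sorted(c.size for c in clusters) == [2, 2]

    def test_is_partition_with_representative_identity(self, default_bundle):
        from tests.conftest import units_of

        units = units_of(default_bundle)
        clusters = greedy_cluster(units)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == sorted(u.uid for u in units)
        seq_of = {u.uid: u.unit_seq for u in units}
        for c in clusters:
            rep = seq_of[c.id]
            for m in c.members:
                assert pairwise_identity(seq_of[m], rep) >= 0.90

    def test_rows_degap_to_sequences(self):
        units = [("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR"), ("c", "MKTAYIAKQQ")]
        (cluster,) = greedy_cluster(units)
        seq_of = dict(units)
        for m, row in zip(cluster.members, cluster.alignment):
            assert row.replace("-", "") == seq_of[m]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            greedy_cluster([("a", "MKT")], threshold=0.0)


class TestBuildProfile:
    def test_delta_columns_without_pseudocounts(self):
        p = build_profile(
            SeqCluster(id="a", members=["a"], alignment=["ACD"]), 0.0
        )
        for c, letter in enumerate("ACD"):
            assert p.columns[c][AA.index(letter)] == pytest.approx(1.0)

    def test_hand_computed_pseudocount_column(self):
        # column "A,A,A,A", pc weight 1, bg(A) = 0.074 -> (4 + 0.074)/5
        cl = SeqCluster(
            id="a", members=list("abcd"), alignment=["A", "A", "A", "A"]
        )
        p = build_profile(cl, 1.0)
        assert p.columns[0][AA.index("A")] == pytest.approx((4 + 0.074) / 5)

    def test_columns_sum_to_one(self, default_bundle):
        from tests.conftest import units_of

        clusters = greedy_cluster(units_of(default_bundle))
        p = build_profile(clusters[0], 1.0)
        assert np.allclose(p.columns.sum(axis=1), 1.0, atol=1e-9)
        assert (p.columns > 0).all()

    def test_all_gap_column_is_background(self):
        cl = SeqCluster(id="a", members=["a", "b"], alignment=["A-", "C-"])
        p = build_profile(cl, 1.0)
        from kinfams._align import BACKGROUND_FREQS

        assert np.allclose(p.columns[1], BACKGROUND_FREQS)

    def test_position_based_weights_sum(self):
        w = position_based_weights(["ACD", "ACD", "AKD"])
        assert w.shape == (3,)
        assert w.sum() == pytest.approx(3.0)  # normalised to sum to n
        assert w[2] > w[0]  # the divergent sequence carries more weight

    def test_empty_alignment_error(self):
        cl = SeqCluster(id="a", members=["a"], alignment=["A"])
        cl.alignment = []
        cl.members = []
        with pytest.raises(ValueError):
            build_profile(cl)


class TestScoreProfiles:
    def _profiles(self, seqs, pc=1.0):
        return [
            build_profile(
                SeqCluster(id=f"p{i}", members=[f"p{i}"], alignment=[s]), pc
            )
            for i, s in enumerate(seqs)
        ]

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        p, q = self._profiles([rand_seq(rng, 30), rand_seq(rng, 25)])
        assert score_profiles(p, q) == pytest.approx(score_profiles(q, p))

    def test_self_score_beats_random(self):
        rng = np.random.default_rng(2)
        base = rand_seq(rng, 40)
        (p,) = self._profiles([base])
        for _ in range(100):
            (q,) = self._profiles([rand_seq(rng, 40)])
            assert score_profiles(p, p) >= score_profiles(p, q)

    def test_single_sequence_profiles_match_plain_alignment(self):
        # pc weight 0 keeps deltas: profile-profile DP equals plain DP score
        s1, s2 = "MKTAYIAKQR", "MKTAHIAKQR"
        p1, p2 = self._profiles([s1, s2], pc=0.0)
        diag = sum(
            BLOSUM62[i, j] for i, j in zip(encode(s1), encode(s2))
        ) / len(s1)
        assert score_profiles(p1, p2) == pytest.approx(diag)


class TestMergeTree:
    def _clusters(self, seqs):
        return [
            SeqCluster(id=f"c{i}", members=[f"c{i}"], alignment=[s])
            for i, s in enumerate(seqs)
        ]

    def test_single_cluster_is_leaf(self):
        tree = build_merge_tree(self._clusters(["MKTAYI"]))
        assert tree.root.is_leaf

    def test_planted_topology(self):
        rng = np.random.default_rng(3)
        fam1 = rand_seq(rng, 60)
        fam2 = rand_seq(rng, 60)
        a = fam1
        b = fam1[:57] + "AAA"  # near-identical to a
        c = fam2
        tree = build_merge_tree(self._clusters([a, b, c]))
        first = min(tree.internal_nodes(), key=lambda n: n.merge_order)
        assert sorted(first.cluster.members) == ["c0", "c1"]

    def test_leaf_and_node_counts(self):
        rng = np.random.default_rng(4)
        tree = build_merge_tree(self._clusters([rand_seq(rng, 30) for _ in range(7)]))
        assert len(tree.leaves) == 7 and len(tree.internal_nodes()) == 6

    def test_merge_orders_strictly_increasing(self):
        rng = np.random.default_rng(8)
        tree = build_merge_tree(self._clusters([rand_seq(rng, 30) for _ in range(6)]))
        orders = sorted(n.merge_order for n in tree.internal_nodes())
        assert orders == list(range(1, 6))

    def test_member_sets_are_disjoint_unions(self):
        rng = np.random.default_rng(9)
        tree = build_merge_tree(self._clusters([rand_seq(rng, 30) for _ in range(5)]))
        for n in tree.internal_nodes():
            left, right = set(n.left.cluster.members), set(n.right.cluster.members)
            assert left.isdisjoint(right)
            assert left | right == set(n.cluster.members)

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(6)
        seqs = [rand_seq(rng, 40) for _ in range(5)]
        trees = []
        for perm in ([0, 1, 2, 3, 4], [4, 2, 0, 3, 1], [1, 0, 4, 2, 3]):
            clusters = [
                SeqCluster(id=f"c{i}", members=[f"c{i}"], alignment=[seqs[i]])
                for i in perm
            ]
            trees.append(build_merge_tree(clusters))

        def signature(tree):
            return sorted(
                (n.merge_order, tuple(sorted(n.cluster.members)))
                for n in tree.internal_nodes()
            )

        assert signature(trees[0]) == signature(trees[1]) == signature(trees[2])

    def test_merged_alignment_round_trip(self):
        rng = np.random.default_rng(10)
        base = rand_seq(rng, 50)
        variants = [base, base[:40] + rand_seq(rng, 12), base[:20] + rand_seq(rng, 30)]
        tree = build_merge_tree(self._clusters(variants))
        for n in tree.leaves + tree.internal_nodes():
            widths = {len(r) for r in n.cluster.alignment}
            assert len(widths) == 1
            for m, row in zip(n.cluster.members, n.cluster.alignment):
                idx = int(m[1:])
                assert row.replace("-", "") == variants[idx]

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            build_merge_tree([])
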