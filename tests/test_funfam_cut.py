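"""SDP detection, cut decisions and the classification driver."""

import numpy as np
import pytest

from kinfams import ClassifyParams, FixtureConfig, generate_superfamily
from kinfams.clustering import SeqCluster, build_merge_tree
from kinfams.funfam_cut import (
    CutParams,
    cut_tree,
    decide_cut,
    detect_sdps,
    group_column_scores,
    similarity,
)
from tests.conftest import classify_bundle


class TestSimilarity:
    def test_diagonal_is_one(self):
        for x in "ACDEFGHIKLMNPQRSTVWY":
            assert similarity(x, x) == pytest.approx(1.0)

    def test_e_vs_a(self):
        # (B62(E,A) + 4) / (B62(E,E) + 4) = 3/9
        assert similarity("E", "A") == pytest.approx(1 / 3)

    def test_w_vs_g(self):
        # max(0, (B62(W,G) + 4) / (B62(W,W) + 4)) = 2/15
        assert similarity("W", "G") == pytest.approx(2 / 15)

    def test_unknown_letter_error(self):
        with pytest.raises(ValueError):
            similarity("X", "A")

    def test_symmetric_and_bounded(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for x in aas:
            for y in aas:
                s = similarity(x, y)
                assert 0.0 <= s <= 1.0
                assert s == similarity(y, x)


class TestGroupColumnScores:
    def test_conserved_different_column(self):
        s = group_column_scores(list("EEEE"), list("AAAA"))
        assert s.cons_a == pytest.approx(1.0)
        assert s.cons_b == pytest.approx(1.0)
        assert s.between == pytest.approx(1 / 3)
        assert s.groupsim == pytest.approx(2 / 3)
        assert s.is_sdp

    def test_identical_columns_not_sdp(self):
        s = group_column_scores(list("KKK"), list("KKK"))
        assert s.groupsim == pytest.approx(0.0)
        assert not s.is_sdp

    def test_unconserved_group_blocks_sdp(self):
        s = group_column_scores(list("EEEE"), list("ADKW"))
        pairs = [("A", "D"), ("A", "K"), ("A", "W"), ("D", "K"), ("D", "W"), ("K", "W")]
        expected = sum(similarity(x, y) for x, y in pairs) / 6
        assert s.cons_b == pytest.approx(expected)
        assert s.cons_b < 0.8
        assert not s.is_sdp

    def test_groupsim_invariant(self):
        s = group_column_scores(list("EEDD"), list("KKRR"))
        assert s.groupsim == pytest.approx(min(s.cons_a, s.cons_b) - s.between)

    def test_gap_fraction_blocks_sdp(self):
        s = group_column_scores(list("E---"), list("AAAA"))
        assert s is None  # fewer than 2 non-gap residues in group A

    def test_majority_gap_column_not_sdp(self):
        s = group_column_scores(list("EE----"), list("AAAAAA"))
        assert s.gapfrac_a == pytest.approx(4 / 6)
        assert not s.is_sdp

    def test_x_treated_as_gap(self):
        s = group_column_scores(list("EEX"), list("AAA"))
        assert s.gapfrac_a == pytest.approx(1 / 3)

    def test_small_group_error(self):
        with pytest.raises(ValueError, match="group too small"):
            group_column_scores(list("E"), list("AA"))


class TestDetectSdps:
    def test_planted_columns_exactly_recovered(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        a_rows, b_rows = [], []
        planted = [2, 10, 17, 25, 30]
        for _ in range(5):
            a = list(base)
            b = list(base)
            for c, (ra, rb) in zip(planted, [("E", "A")] * 5):
                a[c], b[c] = ra, rb
            a_rows.append("".join(a))
            b_rows.append("".join(b))
        scores = detect_sdps(a_rows, b_rows)
        assert {s.position for s in scores if s.is_sdp} == {c + 1 for c in planted}

    def test_identical_alignments_no_sdps(self):
        rows = ["MKTAYIAKQR"] * 4
        assert not any(s.is_sdp for s in detect_sdps(rows, rows))

    def test_sorted_by_groupsim(self):
        base = "MKTAYIAKQRQISFVKSHFSRQ"
        a = [base.replace("Y", "E", 1)] * 4
        b = [base] * 4
        scores = detect_sdps(a, b)
        gs = [s.groupsim for s in scores]
        assert gs == sorted(gs, reverse=True)

    def test_width_mismatch_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            detect_sdps(["AAA"], ["AAAA"])

    def test_jak_like_motif_columns_rank_top(self):
        # catalytic group carries H-R-D and D-F-G motifs; the pseudokinase
        # group substitutes R-D -> G-N and F -> P at the equivalent columns
        background = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"
        cat = list(background)
        pse = list(background)
        # place motifs: HRD at columns 5-7, DFG at columns 20-22
        cat[5:8] = list("HRD")
        pse[5:8] = list("HGN")
        cat[20:23] = list("DFG")
        pse[20:23] = list("DPG")
        cat_rows = ["".join(cat)] * 6
        pse_rows = ["".join(pse)] * 6
        scores = detect_sdps(cat_rows, pse_rows)
        top = {s.position for s in scores[:3]}
        assert top == {7, 8, 22}  # 1-based: R->G, D->N, F->P columns


def _leaf_clusters(groups):
    clusters = []
    for gi, rows in enumerate(groups):
        for si, row in enumerate(rows):
            cid = f"g{gi}s{si}"
            clusters.append(SeqCluster(id=cid, members=[cid], alignment=[row]))
    return clusters


def _two_family_rows(n_per_family=4, n_cols=60, n_diff=5, seed=0):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTV"), size=n_cols))
    cols = rng.choice(n_cols, size=n_diff, replace=False)
    fam_a, fam_b = list(base), list(base)
    for c in cols:
        fam_a[c], fam_b[c] = "E", "A"
    rows_a = ["".join(fam_a)] * n_per_family
    rows_b = ["".join(fam_b)] * n_per_family
    return rows_a, rows_b


class TestDecideCut:
    def _root(self, rows_a, rows_b):
        tree = build_merge_tree(_leaf_clusters([rows_a, rows_b]), 0.01)
        return tree.root

    def test_planted_families_cut(self):
        rows_a, rows_b = _two_family_rows(n_per_family=6)
        assert decide_cut(self._root(rows_a, rows_b))

    def test_singleton_child_never_cuts(self):
        rows_a, rows_b = _two_family_rows()
        assert not decide_cut(self._root(rows_a[:1], rows_b))

    def test_identical_children_never_cut(self):
        rows, _ = _two_family_rows()
        assert not decide_cut(self._root(rows[:4], rows[:4]))

    def test_leaf_error(self):
        tree = build_merge_tree(_leaf_clusters([["MKTAYI"]]), 0.01)
        with pytest.raises(ValueError):
            decide_cut(tree.root)

    def test_small_low_diversity_children_need_double_evidence(self):
        # 3-member, low-diversity children: 5 SDPs >= 2*k_min -> cut,
        # but with only 3 planted columns (< 2*k_min=4) -> no cut
        rows_a5, rows_b5 = _two_family_rows(n_per_family=3, n_diff=5)
        rows_a3, rows_b3 = _two_family_rows(n_per_family=3, n_diff=3)
        assert decide_cut(self._root(rows_a5, rows_b5))
        assert not decide_cut(self._root(rows_a3, rows_b3))


class TestCutTree:
    def test_no_cut_single_family(self):
        rows, _ = _two_family_rows()
        tree = build_merge_tree(_leaf_clusters([rows]), 0.01)
        funfams = cut_tree(tree, CutParams(), 0.01)
        assert len(funfams) == 1
        assert funfams[0].size == len(rows)

    def test_one_column_families_merge(self):
        rows_a, rows_b = _two_family_rows(n_per_family=6, n_diff=1)
        tree = build_merge_tree(_leaf_clusters([rows_a, rows_b]), 0.01)
        assert len(cut_tree(tree, CutParams(), 0.01)) == 1

    def test_planted_families_separate_with_sdp_report(self):
        rows_a, rows_b = _two_family_rows(n_per_family=6, n_diff=5)
        tree = build_merge_tree(_leaf_clusters([rows_a, rows_b]), 0.01)
        funfams = cut_tree(tree, CutParams(), 0.01)
        assert len(funfams) == 2
        for ff in funfams:
            assert len([s for s in ff.sdps_vs_sibling if s.is_sdp]) == 5

    def test_output_is_partition(self):
        rows_a, rows_b = _two_family_rows(n_per_family=5)
        clusters = _leaf_clusters([rows_a, rows_b])
        tree = build_merge_tree(clusters, 0.01)
        funfams = cut_tree(tree, CutParams(), 0.01)
        got = sorted(m for ff in funfams for m in ff.members)
        assert got == sorted(c.id for c in clusters)


class TestClassifySuperfamily:
    def test_single_family_single_funfam(self):
        bundle = generate_superfamily(FixtureConfig(seed=3, n_families=1))
        result = classify_bundle(bundle)
        assert len(result.funfams) == 1

    def test_six_family_fixture_recovers_partition(self, default_bundle, default_result):
        truth = default_bundle.truth.family_by_seq
        assert len(default_result.funfams) == 6
        for ff in default_result.funfams:
            fams = {truth[m.split("/")[0]] for m in ff.members}
            assert len(fams) == 1

    def test_pooling_merges_family_split_across_mdas(self):
        bundle = generate_superfamily(
            FixtureConfig(seed=5, split_family_across_mdas=True)
        )
        result = classify_bundle(bundle)
        truth = bundle.truth.family_by_seq
        fam0 = [
            ff
            for ff in result.funfams
            if {truth[m.split("/")[0]] for m in ff.members} == {0}
        ]
        assert len(fam0) == 1
        assert len(fam0[0].mda_set) == 2  # both architectures pooled

    def test_unannotated_clusters_held_out_and_assigned(self, default_bundle, default_result):
        exp = dict(
            zip(default_bundle.annotations.seq_id, default_bundle.annotations.experimental)
        )
        held_ids = {m for cl in default_result.held_out for m in cl.members}
        # held-out clusters contain no experimentally annotated sequence
        for cl in default_result.held_out:
            assert not any(exp[m.split("/")[0]] for m in cl.members)
        # classified members never come from held-out clusters
        classified = {m for ff in default_result.funfams for m in ff.members}
        assert classified.isdisjoint(held_ids)
        # every held-out cluster gets an advisory assignment to its true family
        truth = default_bundle.truth.family_by_seq
        assert len(default_result.unannotated_assignments) == len(default_result.held_out)
        fam_of_ff = {
            ff.id: {truth[m.split("/")[0]] for m in ff.members}.pop()
            for ff in default_result.funfams
        }
        for a in default_result.unannotated_assignments:
            cluster = next(
                cl for cl in default_result.held_out if cl.id == a.cluster_id
            )
            true_fams = {truth[m.split("/")[0]] for m in cluster.members}
            assert fam_of_ff[a.funfam_id] in true_fams

    def test_monotonicity_in_k_min(self, default_bundle):
        counts = []
        for k_min in (1, 2, 4, 6):
            params = ClassifyParams(cut=CutParams(k_min=k_min))
            counts.append(len(classify_bundle(default_bundle, params).funfams))
        assert counts == sorted(counts, reverse=True)
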