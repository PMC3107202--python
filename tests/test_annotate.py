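"""Junction decomposition: anchoring, microhomology, insertions, summaries."""

import numpy as np
import pytest
from helpers import annotation_as_dict, oracle_decompose, random_junction_case

from altej.annotate import (
    Junction,
    JunctionAnnotation,
    UnalignableJunction,
    anchor,
    annotate_junction,
    derive_insertion,
    summarize_genotype,
)
from altej.references import ReferenceLocus, build_derivative, revcomp
from conftest import make_random_derivative


def _junction(seq, der, jid="j1", genotype="g"):
    return Junction(id=jid, genotype=genotype, derivative=der.name, sequence=seq)


@pytest.fixture
def engineered_der():
    """Derivative crafted so a 3/2-nt deletion junction shows exactly 2 nt
    of junctional microhomology ('CA' shared by both retained ends)."""
    left = ReferenceLocus(
        name="eL", sequence="TATGGCAGTCGCATTGACCAGGC", nick_top=19, nick_bottom=23
    )
    right = ReferenceLocus(
        name="eR", sequence="TGCAGTCATTCGGAGCTTAGCAAC", nick_top=4, nick_bottom=8
    )
    return build_derivative(left, right, name="der_eng")


class TestAnchor:
    def test_perfect_join_anchors_forward_with_full_coverage(self, toy_der):
        res = anchor(toy_der.perfect_join, toy_der)
        assert res.orientation == "forward"
        assert res.left_match_len + res.right_match_len >= len(toy_der.perfect_join)

    def test_reverse_complement_detected_with_same_lengths(self, toy_der):
        fwd = anchor(toy_der.perfect_join, toy_der)
        rev = anchor(revcomp(toy_der.perfect_join), toy_der)
        assert rev.orientation == "reverse"
        assert (rev.left_match_len, rev.right_match_len) == (
            fwd.left_match_len,
            fwd.right_match_len,
        )

    def test_unrelated_sequence_is_unalignable(self, toy_der):
        with pytest.raises(UnalignableJunction):
            anchor("AAAA" + "GGGG", toy_der)

    def test_seed_len_floor(self, toy_der):
        with pytest.raises(ValueError, match="seed_len"):
            anchor(toy_der.perfect_join, toy_der, seed_len=4)


class TestAnnotateJunction:
    def test_perfect_join_on_homology_free_toys(self, toy_der):
        ann = annotate_junction(_junction(toy_der.perfect_join, toy_der), toy_der)
        assert (ann.del_left, ann.del_right, ann.mh_len) == (0, 0, 0)
        assert ann.insertion_len == 0
        assert ann.junction_class == "perfect"
        assert annotation_as_dict(ann) == oracle_decompose(toy_der.perfect_join, toy_der)

    def test_engineered_deletion_with_two_base_microhomology(self, engineered_der):
        der = engineered_der
        # delete 3 nt from the left end, 2 from the right; the shared 'CA'
        # is written once and charged to neither deletion
        seq = der.left_fragment[:20] + der.right_fragment[4:]
        ann = annotate_junction(_junction(seq, der), der)
        assert (ann.del_left, ann.del_right) == (3, 2)
        assert (ann.mh_len, ann.mh_seq) == (2, "CA")
        assert ann.insertion_len == 0
        assert ann.junction_class == "simple_deletion"
        assert annotation_as_dict(ann) == oracle_decompose(seq, der)

    def test_untemplated_insert_at_the_joint(self, toy_der):
        seq = toy_der.left_fragment + "TTAGGC" + toy_der.right_fragment
        ann = annotate_junction(_junction(seq, toy_der), toy_der)
        assert ann.insertion_seq == "TTAGGC"
        assert ann.mh_len == 0
        assert (ann.del_left, ann.del_right) == (0, 0)
        assert ann.junction_class == "insertion"
        assert annotation_as_dict(ann) == oracle_decompose(seq, toy_der)

    def test_reverse_complement_read_yields_identical_annotation(self, engineered_der):
        der = engineered_der
        seq = der.left_fragment[:20] + der.right_fragment[4:]
        fwd = annotate_junction(_junction(seq, der), der)
        rev = annotate_junction(_junction(revcomp(seq), der), der)
        assert rev.orientation == "reverse"
        assert annotation_as_dict(rev) == annotation_as_dict(fwd)

    def test_reconstruction_is_byte_exact(self, rng):
        der = make_random_derivative(rng, length=200)
        for _ in range(100):
            seq = random_junction_case(rng, der)
            ann = annotate_junction(_junction(seq, der), der)
            assert ann.reconstruct(der) == seq

    def test_matches_exhaustive_oracle_on_randomized_junctions(self, rng):
        for _ in range(10):
            der = make_random_derivative(rng, length=int(rng.integers(120, 201)))
            for _ in range(30):
                seq = random_junction_case(rng, der)
                ann = annotate_junction(_junction(seq, der), der)
                assert annotation_as_dict(ann) == oracle_decompose(seq, der)

    def test_extending_reference_flanks_does_not_change_annotation(self, rng):
        der = make_random_derivative(rng, length=200)
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        left2 = ReferenceLocus(
            name="L2",
            sequence=pad + der.left.sequence,
            nick_top=der.left.nick_top + 40,
            nick_bottom=der.left.nick_bottom + 40,
        )
        right2 = ReferenceLocus(
            name="R2",
            sequence=der.right.sequence + pad,
            nick_top=der.right.nick_top,
            nick_bottom=der.right.nick_bottom,
        )
        der2 = build_derivative(left2, right2, name="der_ext")
        for _ in range(50):
            seq = random_junction_case(rng, der)
            a1 = annotation_as_dict(annotate_junction(_junction(seq, der), der))
            a2 = annotation_as_dict(annotate_junction(_junction(seq, der2), der2))
            assert a1 == a2


class TestTerminalBaseRule:
    @pytest.fixture
    def der_variable_g(self, rng):
        while True:
            der = make_random_derivative(rng, length=120)
            if der.right_fragment[0] == "G" and der.left_fragment[-1] != "G":
                break
        right = ReferenceLocus(
            name=der.right.name,
            sequence=der.right.sequence,
            nick_top=der.right.nick_top,
            nick_bottom=der.right.nick_bottom,
            variable_terminal_bases=1,
        )
        return build_derivative(der.left, right, name="der_vg")

    def test_single_terminal_base_copy_not_scored_as_insertion(self, der_variable_g):
        der = der_variable_g
        seq = der.left_fragment + "G" + der.right_fragment
        ann = annotate_junction(_junction(seq, der), der)
        assert ann.terminal_rule_applied
        assert ann.insertion_len == 0
        assert ann.junction_class == "perfect"
        assert ann.reconstruct(der) == seq
        assert annotation_as_dict(ann) == oracle_decompose(seq, der)

    def test_excess_terminal_copies_still_scored_as_insertion(self, der_variable_g):
        der = der_variable_g
        seq = der.left_fragment + "GG" + der.right_fragment
        ann = annotate_junction(_junction(seq, der), der)
        assert not ann.terminal_rule_applied
        assert ann.insertion_seq == "GG"
        assert annotation_as_dict(ann) == oracle_decompose(seq, der)


class TestDeriveInsertion:
    @pytest.fixture
    def planted(self, rng):
        """Derivative plus a junction carrying an insert copied from the
        left locus at a known position (verified unique by scan)."""
        while True:
            der = make_random_derivative(rng, length=200)
            insert = der.left.sequence[10:22]
            genome = der.left.sequence + " " + der.right.sequence
            if genome.count(insert) == 1 and revcomp(insert) not in genome:
                return der, insert

    def test_forward_copy_from_left_locus(self, planted):
        der, insert = planted
        seq = der.left_fragment + insert + der.right_fragment
        ann = annotate_junction(_junction(seq, der), der)
        assert ann.insertion_seq == insert
        deriv = derive_insertion(ann, der)
        assert deriv.source == "left_locus"
        assert not deriv.inverted
        assert (deriv.source_start, deriv.source_end) == (10, 22)

    def test_inverted_copy_from_right_locus(self, rng):
        while True:
            der = make_random_derivative(rng, length=200)
            segment = der.right.sequence[30:41]
            insert = revcomp(segment)
            genome = der.left.sequence + " " + der.right.sequence
            if genome.count(insert) == 0 and genome.count(segment) == 1:
                break
        seq = der.left_fragment + insert + der.right_fragment
        ann = annotate_junction(_junction(seq, der), der)
        deriv = derive_insertion(ann, der)
        assert deriv.source == "right_locus"
        assert deriv.inverted
        assert (deriv.source_start, deriv.source_end) == (30, 41)

    def test_unmatched_insert_is_unknown(self, rng):
        while True:
            der = make_random_derivative(rng, length=150)
            insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=12))
            genome = der.left.sequence + " " + der.right.sequence
            if insert not in genome and revcomp(insert) not in genome:
                break
        seq = der.left_fragment + insert + der.right_fragment
        ann = annotate_junction(_junction(seq, der), der)
        deriv = derive_insertion(ann, der)
        assert deriv.source == "unknown"
        assert deriv.source_start is None

    def test_short_insert_precondition(self, toy_der):
        seq = toy_der.left_fragment + "TTAGGC" + toy_der.right_fragment
        ann = annotate_junction(_junction(seq, toy_der), toy_der)
        with pytest.raises(ValueError, match="min_len"):
            derive_insertion(ann, toy_der, min_len=7)

    def test_flanking_microhomology_at_insert_edge(self, rng):
        while True:
            der = make_random_derivative(rng, length=200)
            tail2 = der.left_fragment[-2:]
            body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))
            insert = tail2 + body
            # guard against longer coincidental repeats or absorbed edges
            if (
                insert[:3] != der.left_fragment[-3:]
                and body[-1] != der.right_fragment[0]
                and tail2[0] != tail2[1]
            ):
                break
        seq = der.left_fragment + insert + der.right_fragment
        ann = annotate_junction(_junction(seq, der), der)
        assert ann.insertion_seq == insert
        deriv = derive_insertion(ann, der, min_len=7)
        assert deriv.flanking_mh_left == 2


def _mk_ann(jid, genotype="g", del_left=0, del_right=0, mh=0, insert=""):
    mh_seq = "A" * mh
    if insert:
        klass = "insertion"
    elif del_left + del_right == 0:
        klass = "perfect"
    else:
        klass = "simple_deletion"
    return JunctionAnnotation(
        junction_id=jid, genotype=genotype, derivative="d",
        del_left=del_left, del_right=del_right, mh_len=mh, mh_seq=mh_seq,
        insertion_seq=insert, junction_class=klass, terminal_rule_applied=False,
        orientation="forward", left_start=0, left_match_end=0,
        right_match_start=0, right_match_len=0,
    )


class TestSummarizeGenotype:
    def test_percent_without_microhomology(self):
        anns = [_mk_ann(f"j{i}", del_left=1, mh=(0 if i < 4 else 1)) for i in range(10)]
        s = summarize_genotype(anns)
        assert s.pct_without_mh == pytest.approx(40.0)
        assert s.n == 10

    def test_all_perfect_joins_have_no_microhomology(self):
        anns = [_mk_ann(f"j{i}") for i in range(5)]
        s = summarize_genotype(anns)
        assert s.pct_without_mh == 100.0
        assert s.n_simple_deletion == 0
        assert s.median_del_total is None

    def test_median_insertion_length_order_statistic(self):
        anns = [
            _mk_ann("a", insert="A" * 4),
            _mk_ann("b", insert="A" * 75),
            _mk_ann("c", insert="A" * 75),
        ]
        s = summarize_genotype(anns)
        assert s.median_insertion_len == 75
        assert s.pct_with_insertions == 100.0
        assert s.pct_long_insertions == pytest.approx(100.0 * 2 / 3)

    def test_microhomology_distribution_excludes_insertions_and_perfect(self):
        anns = [
            _mk_ann("a", del_left=2, mh=2),
            _mk_ann("b", del_left=1, mh=0),
            _mk_ann("c", insert="TT"),
            _mk_ann("d"),
        ]
        s = summarize_genotype(anns)
        assert s.mh_distribution == {0: 1, 2: 1}
        assert s.n_simple_deletion == 2
        assert s.median_del_total == 1.5

    def test_empty_and_mixed_genotypes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_genotype([])
        with pytest.raises(ValueError, match="single genotype"):
            summarize_genotype([_mk_ann("a", genotype="x"), _mk_ann("b", genotype="y")])
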