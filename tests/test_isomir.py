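import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isomirseq import (
    AlignmentCandidate,
    CollapsedRead,
    IsomiRCategory,
    SimConfig,
    TailKind,
    classify_candidate,
    classify_read,
    enumerate_candidates,
    make_reference,
    seed_of,
    seed_shift,
    select_best_candidate,
    simulate_reads,
)
from isomirseq.isomir import classify_tail

from _oracle import oracle_best
from conftest import M5, collapsed


def cand(name="m5", off5=0, off3=0, subs=(), ext3=0, tail=""):
    return AlignmentCandidate(name, off5, off3, tuple(subs), ext3, tail)


class TestEnumerateCandidates:
    def test_exact_match(self, mature5, h1):
        cands = enumerate_candidates(M5, mature5, h1)
        exact = [c for c in cands if c.offset5 == 0 and c.offset3 == 0]
        assert len(exact) == 1
        assert exact[0].substitutions == ()

    def test_templated_3p_extension(self, mature5, h1):
        """m5+GG extends along the hairpin loop (H1[25:27] == GG)."""
        cands = enumerate_candidates(M5 + "GG", mature5, h1)
        hit = next(c for c in cands if c.offset5 == 0)
        assert (hit.offset3, hit.templated_ext3, hit.nta_tail) == (2, 2, "")
        assert hit.substitutions == ()

    def test_nontemplated_3p_tail(self, mature5, h1):
        """m5+AA cannot extend along the template (H1[25] == G), so AA is NTA."""
        cands = enumerate_candidates(M5 + "AA", mature5, h1)
        hit = next(c for c in cands if c.offset5 == 0)
        assert (hit.offset3, hit.templated_ext3, hit.nta_tail) == (2, 0, "AA")

    def test_5p_extension_must_be_templated(self, mature5, h1):
        # H1[2] == 'T', so T+m5 is a valid templated 5' extension but G+m5 is not
        ok = enumerate_candidates("T" + M5, mature5, h1)
        assert any(c.offset5 == -1 and not c.substitutions for c in ok)
        bad = enumerate_candidates("G" + M5, mature5, h1)
        assert not any(c.offset5 == -1 and not c.substitutions for c in bad)

    def test_substitutions_counted_in_body_only(self, mature5, h1):
        read = M5[:10] + ("A" if M5[10] != "A" else "C") + M5[11:] + "AA"
        hit = next(
            c for c in enumerate_candidates(read, mature5, h1) if c.offset5 == 0
        )
        assert len(hit.substitutions) == 1
        assert hit.nta_tail == "AA"


class TestSelectBest:
    def test_fewer_substitutions_win(self):
        a = cand(off5=0, off3=0)
        b = cand(off5=1, off3=-1, subs=[(0, "A", "C"), (1, "C", "G")])
        assert select_best_candidate([b, a]) == a

    def test_templated_beats_nta_tail(self):
        templated = cand(off3=2, ext3=2, tail="")
        nta = cand(off3=2, ext3=0, tail="GG")
        assert select_best_candidate([nta, templated]) == templated

    def test_mature_name_breaks_ties(self):
        a = cand(name="mB")
        b = cand(name="mA")
        assert select_best_candidate([a, b]).mature_name == "mA"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_best_candidate([])


class TestClassifyCandidate:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(), IsomiRCategory.CANONICAL),
            (dict(subs=[(3, "A", "G")]), IsomiRCategory.SUBSTITUTION),
            (dict(off3=-2), IsomiRCategory.DEL3P),
            (dict(off3=2, ext3=0, tail="AA"), IsomiRCategory.ADD3P),
            (dict(off3=2, ext3=2), IsomiRCategory.ADD3P),
            (dict(off5=1), IsomiRCategory.DEL5P),
            (dict(off5=-1), IsomiRCategory.ADD5P),
            (dict(off5=1, off3=2, tail="AA"), IsomiRCategory.MIXED),
            (dict(off5=-1, subs=[(5, "A", "T")]), IsomiRCategory.MIXED),
            (dict(off3=-1, subs=[(5, "A", "T")]), IsomiRCategory.MIXED),
        ],
    )
    def test_seven_way_mapping(self, kwargs, expected):
        assert classify_candidate(cand(**kwargs)) == expected


class TestClassifyRead:
    def test_canonical_call_and_seed(self, toy_ref):
        calls = classify_read(collapsed(M5), toy_ref)
        assert len(calls) == 1
        call = calls[0]
        assert call.category == IsomiRCategory.CANONICAL
        assert call.candidate.mature_name == "m5"
        assert call.seed == "CGTACGT"
        assert call.assigned_fraction == 1.0

    def test_templated_5p_addition(self, toy_ref):
        calls = classify_read(collapsed("T" + M5), toy_ref)
        assert calls[0].category == IsomiRCategory.ADD5P
        assert calls[0].candidate.offset5 == -1

    def test_del5p(self, toy_ref):
        calls = classify_read(collapsed(M5[1:]), toy_ref)
        assert calls[0].category == IsomiRCategory.DEL5P
        assert calls[0].candidate.offset5 == 1
        assert calls[0].seed == seed_of(M5[1:]) == "GTACGTA"

    def test_mixed_del5p_plus_tail(self, toy_ref):
        calls = classify_read(collapsed(M5[1:] + "AA"), toy_ref)
        assert calls[0].category == IsomiRCategory.MIXED
        assert calls[0].candidate.offset5 == 1
        assert calls[0].candidate.offset3 == 2
        assert calls[0].candidate.nta_tail == "AA"

    def test_unmatched_read_unassigned(self, toy_ref):
        assert classify_read(collapsed("TGCA" * 5 + "TG"), toy_ref) == []

    def test_exact_tie_splits_fraction(self):
        # two hairpins sharing an identical mature sequence
        from isomirseq import HairpinRecord, MatureAnnotation, ReferenceSet

        core = "ACGTTGCAGGCCTTAGACGATC"
        hp1 = HairpinRecord("HA", "TTTT" + core + "GGGGTTTTGGGGTTTTGGGGACGTACGTAACCGGTT")
        hp2 = HairpinRecord("HB", "CCCC" + core + "AAAACCCCAAAACCCCAAAATTGGCCAATTGGCCAA")
        ref = ReferenceSet(
            hairpins={"HA": hp1, "HB": hp2},
            matures=[
                MatureAnnotation("ma", "HA", 4, 26, "5p", core),
                MatureAnnotation("mb", "HB", 4, 26, "5p", core),
            ],
        )
        calls = classify_read(collapsed(core, count=4), ref)
        assert len(calls) == 2
        assert [c.assigned_fraction for c in calls] == [0.5, 0.5]
        assert [c.candidate.mature_name for c in calls] == ["ma", "mb"]


class TestSeed:
    def test_seed_positions_2_to_8(self):
        assert seed_of(M5) == "CGTACGT"
        assert seed_of(M5[1:]) == "GTACGTA"

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            seed_of("ACGTACG")

    def test_seed_shift_follows_offset5(self, toy_ref):
        del5 = classify_read(collapsed(M5[1:]), toy_ref)[0]
        assert seed_shift(del5) == 1
        add3 = classify_read(collapsed(M5 + "AA"), toy_ref)[0]
        assert seed_shift(add3) == 0
        add5 = classify_read(collapsed("TT" + M5), toy_ref)[0]
        assert seed_shift(add5) == -2
        # the shifted seed equals the hairpin-extended window at positions 2-8
        hp = toy_ref.hairpins["H1"].sequence
        s = toy_ref.mature_by_name("m5").start - 2
        assert add5.seed == hp[s + 1 : s + 8]


class TestTailCall:
    @given(
        tail=st.text(alphabet="ACGT", min_size=0, max_size=5),
        off3=st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nta_consistency(self, tail, off3):
        """adenylated iff tail nonempty all-A; uridylated iff all-T."""
        off3 = max(off3, len(tail))
        c = cand(off3=off3, ext3=off3 - len(tail), tail=tail)
        kind = classify_tail(c)
        if not tail:
            assert kind in (TailKind.TEMPLATED, TailKind.NONE)
            assert (kind == TailKind.TEMPLATED) == (off3 > 0)
        elif set(tail) == {"A"}:
            assert kind == TailKind.ADENYLATED
        elif set(tail) == {"T"}:
            assert kind == TailKind.URIDYLATED
        else:
            assert kind == TailKind.OTHER


class TestOracleEquivalence:
    def test_classifier_matches_brute_force(self):
        """Minimal-edit interpretation equals exhaustive enumeration."""
        ref = make_reference(8, 11)
        cfg = SimConfig(n_reads=300, rng_seed=12)
        for rid, seq, truth in simulate_reads(ref, cfg):
            calls = classify_read(CollapsedRead(seq, 1, "s"), ref)
            expect = oracle_best(seq, ref)
            assert calls, f"unassigned read {seq}"
            got = calls[0]
            assert got.category.value == expect["category"]
            assert got.candidate.offset5 == expect["offset5"]
            assert got.candidate.offset3 == expect["offset3"]
            assert got.candidate.nta_tail == expect["tail"]

    def test_exhaustiveness_counts(self, toy_ref):
        """Every read lands in exactly one category or is unassigned."""
        from isomirseq import classify_library

        reads = [
            collapsed(M5),
            collapsed(M5[1:]),
            collapsed(M5 + "AA"),
            collapsed("TGCA" * 5 + "TG"),
        ]
        calls, unassigned = classify_library(reads, toy_ref)
        assert len(calls) + len(unassigned) == len(reads)
        assert all(isinstance(c.category, IsomiRCategory) for c in calls)
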