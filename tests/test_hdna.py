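import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonbscan import (
    HdnaParams,
    SequenceRecord,
    brute_force_mirror_repeats,
    find_mirror_repeats,
    find_purity_tracts,
)
from nonbscan.hdna import find_purity_tracts_typed

from conftest import random_record


def geometries(hits):
    return [h.geometry() for h in hits]


class TestPurityTracts:
    def test_hand_enumerated_runs(self):
        rec = SequenceRecord("s", "AGGAAGCTCT")
        tracts = find_purity_tracts_typed(rec, 3)
        assert [(iv.start, iv.end, t) for iv, t in tracts] == [
            (0, 6, "purine"),
            (6, 10, "pyrimidine"),
        ]

    def test_alternation_breaks_purity(self):
        assert find_purity_tracts(SequenceRecord("s", "ACACAC"), 3) == []

    def test_n_terminates_runs(self):
        tracts = find_purity_tracts(SequenceRecord("s", "AAANAAA"), 3)
        assert [(iv.start, iv.end) for iv in tracts] == [(0, 3), (4, 7)]

    def test_runs_are_maximal(self):
        # a reported run must not be extendable on either side
        rec = random_record(11, length=400)
        for iv, ttype in find_purity_tracts_typed(rec, 4):
            pure = set("AG") if ttype == "purine" else set("CT")
            assert set(rec.seq[iv.start : iv.end]) <= pure
            if iv.start > 0:
                assert rec.seq[iv.start - 1] not in pure
            if iv.end < rec.length:
                assert rec.seq[iv.end] not in pure


class TestFindMirrorRepeats:
    def test_impure_spacer_tolerated_at_defaults(self):
        # arms are each pure purine; the 1 bp pyrimidine spacer is allowed
        rec = SequenceRecord("s", "TTAAGGAGTGAGGAATT")
        (hit,) = find_mirror_repeats(rec)
        assert hit.interval.start == 2 and hit.interval.end == 15
        assert hit.arm1_seq == "AAGGAG"
        assert hit.spacer_seq == "T"
        assert hit.arm2_seq == "GAGGAA"
        assert hit.arm2_seq == hit.arm1_seq[::-1]
        assert (hit.arm_len, hit.spacer_len, hit.mismatches) == (6, 1, 0)
        assert hit.tract_type == "purine"

    def test_pure_spacer_flag_excludes_impure_spacer(self):
        rec = SequenceRecord("s", "TTAAGGAGTGAGGAATT")
        assert find_mirror_repeats(rec, HdnaParams(require_pure_spacer=True)) == []

    def test_arm_below_minimum_not_reported(self):
        rec = SequenceRecord("s", "AAGGAGTGAGGAA")
        assert find_mirror_repeats(rec, HdnaParams(min_arm=7)) == []

    def test_one_mismatch_allowed_only_for_long_arms(self):
        # a 10 bp arm pair with one purine-purine symmetry mismatch is a hit;
        # the same construct with 9 bp arms is not (and yields no shorter
        # mismatch-free hit, because the mismatch sits mid-arm)
        arm1 = "AAGGAGGAGG"
        arm2 = list(arm1[::-1])
        arm2[5] = "A" if arm2[5] == "G" else "G"
        rec10 = SequenceRecord("s", "TT" + arm1 + "C" + "".join(arm2) + "TT")
        (hit,) = find_mirror_repeats(rec10)
        assert (hit.arm_len, hit.mismatches) == (10, 1)

        arm1b = arm1[1:]
        arm2b = list(arm1b[::-1])
        arm2b[4] = "A" if arm2b[4] == "G" else "G"
        rec9 = SequenceRecord("s", "TT" + arm1b + "C" + "".join(arm2b) + "TT")
        assert find_mirror_repeats(rec9) == []

    def test_mismatched_base_must_keep_purity(self):
        # a pyrimidine inside an otherwise purine arm is not a "mismatch";
        # it truncates the arm below the minimum instead
        arm1 = "AAGGAGGAGG"
        arm2 = list(arm1[::-1])
        arm2[5] = "T"  # impure
        rec = SequenceRecord("s", "TT" + arm1 + "C" + "".join(arm2) + "TT")
        for hit in find_mirror_repeats(rec):
            assert set(hit.arm1_seq + hit.arm2_seq) <= set("AG") or set(
                hit.arm1_seq + hit.arm2_seq
            ) <= set("CT")

    def test_short_sequence_returns_empty(self):
        assert find_mirror_repeats(SequenceRecord("s", "AAGGA")) == []
        assert find_mirror_repeats(SequenceRecord("s", "")) == []

    def test_poly_purine_run_yields_hits_and_matches_oracle(self):
        rec = SequenceRecord("s", "A" * 30)
        fast = geometries(find_mirror_repeats(rec))
        brute = geometries(brute_force_mirror_repeats(rec))
        assert fast == brute
        assert len(fast) > 0

    def test_output_ordering(self):
        rec = random_record(5, length=500, gc=0.3)
        hits = find_mirror_repeats(rec)
        keys = [(h.interval.start, -h.arm_len, h.spacer_len) for h in hits]
        assert keys == sorted(keys)


class TestHitInvariants:
    """Structural invariants on every reported hit, over random sequences."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_rules_hold(self, seed):
        params = HdnaParams()
        rec = random_record(1000 + seed)
        for h in find_mirror_repeats(rec, params):
            assert len(h.interval) == 2 * h.arm_len + h.spacer_len
            assert h.arm_len >= params.min_arm
            assert params.min_spacer <= h.spacer_len <= params.max_spacer
            pure = set("AG") if h.tract_type == "purine" else set("CT")
            assert set(h.arm1_seq) <= pure and set(h.arm2_seq) <= pure
            n_mm = sum(a != b for a, b in zip(h.arm1_seq, h.arm2_seq[::-1]))
            assert n_mm == h.mismatches <= params.max_mismatches
            if h.mismatches > 0:
                assert h.arm_len >= params.mismatch_arm_threshold
            s, q = h.interval.start, h.interval.start + h.arm_len
            assert rec.seq[s:q] == h.arm1_seq
            assert rec.seq[q : q + h.spacer_len] == h.spacer_seq

    @pytest.mark.parametrize("seed", range(15))
    def test_strand_symmetry(self, seed):
        """Mirror geometry is preserved on the reverse complement (purity swaps)."""
        rec = random_record(2000 + seed, length=300)
        L = rec.length
        fwd = {
            (L - h.interval.end, L - h.interval.start, h.arm_len, h.spacer_len,
             h.mismatches)
            for h in find_mirror_repeats(rec)
        }
        rev = {
            (h.interval.start, h.interval.end, h.arm_len, h.spacer_len, h.mismatches)
            for h in find_mirror_repeats(rec.reverse_complement())
        }
        assert fwd == rev


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_sequences(self, seed):
        rec = random_record(3000 + seed)
        assert geometries(find_mirror_repeats(rec)) == geometries(
            brute_force_mirror_repeats(rec)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_with_n_bases(self, seed):
        rng = np.random.default_rng(4000 + seed)
        seq = "".join(
            rng.choice(list("ACGTN"), size=200, p=[0.24, 0.24, 0.24, 0.24, 0.04])
        )
        rec = SequenceRecord("n", seq)
        assert geometries(find_mirror_repeats(rec)) == geometries(
            brute_force_mirror_repeats(rec)
        )

    @given(st.text(alphabet="AGCTN", min_size=0, max_size=60))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_hypothesis_small_sequences(self, seq):
        rec = SequenceRecord("h", seq)
        assert geometries(find_mirror_repeats(rec)) == geometries(
            brute_force_mirror_repeats(rec)
        )

    @given(st.text(alphabet="AG", min_size=0, max_size=40))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_hypothesis_purine_runs_worst_case(self, seq):
        # near-homopolymer inputs stress maximality + suppression
        rec = SequenceRecord("h", seq)
        assert geometries(find_mirror_repeats(rec)) == geometries(
            brute_force_mirror_repeats(rec)
        )
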