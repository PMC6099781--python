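"""Dispersed-repeat and SSR scanners against planted cases and brute force."""

import numpy as np
import pytest

from conftest import random_seq
from oracles import repeat_oracle, ssr_oracle
from plastocompare.plastome_io import CircularGenome, revcomp
from plastocompare.repeat_scan import (MIN_COPIES, find_repeats, find_ssrs,
                                       repeat_summary)


def as_triples(hits, rtype):
    return {(h.pos1.start, h.pos2.start, h.length)
            for h in hits if h.rtype == rtype}


class TestFindRepeats:
    def test_planted_forward_duplicate(self):
        # a 7-mer duplicated once inside hand-picked repeat-free flanks
        core = "TTAGGCA"
        seq = core + "CCGGCCGTACGCG" + core + "GGTTGGTCAAGTC"
        g = CircularGenome("toy", seq)
        hits = find_repeats(g, min_repeat_len=7, types=("forward",))
        assert [(h.pos1.start, h.pos2.start, h.length) for h in hits] == \
               [(0, 20, 7)]

    def test_planted_palindromic(self, rng):
        seg = random_seq(rng, 25)
        # 'A' guard bases at the copy flanks block any chance extension
        seq = (random_seq(rng, 29) + "A" + seg + "A" + random_seq(rng, 28)
               + "A" + revcomp(seg) + "A" + random_seq(rng, 29))
        g = CircularGenome("toy", seq)
        pal = find_repeats(g, min_repeat_len=20, types=("palindromic",))
        assert [(h.pos1.start, h.pos2.start, h.length) for h in pal] == \
               [(30, 85, 25)]

    def test_min_len_validation(self, rng):
        g = CircularGenome("g", random_seq(rng, 100))
        with pytest.raises(ValueError):
            find_repeats(g, min_repeat_len=1)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 700)
        g = CircularGenome("r", seq)
        hits = find_repeats(g, min_repeat_len=8)
        expected = repeat_oracle(seq, 8)
        for t in ("forward", "palindromic", "reverse", "complement"):
            assert as_triples(hits, t) == expected[t], t

    def test_oracle_equivalence_with_n(self, rng):
        seq = random_seq(rng, 400, "ACGTN")
        g = CircularGenome("n", seq)
        hits = find_repeats(g, min_repeat_len=6)
        expected = repeat_oracle(seq, 6)
        for t in ("forward", "palindromic", "reverse", "complement"):
            assert as_triples(hits, t) == expected[t], t

    def test_strand_covariance(self, rng):
        seq = random_seq(rng, 600)
        g = CircularGenome("f", seq)
        g_rc = CircularGenome("r", revcomp(seq))
        n = len(seq)
        fwd = as_triples(find_repeats(g, 8, types=("forward",)), "forward")
        fwd_rc = as_triples(find_repeats(g_rc, 8, types=("forward",)),
                            "forward")
        mirrored = {(n - (j + L), n - (i + L), L) for i, j, L in fwd}
        assert fwd_rc == mirrored
        pal = as_triples(find_repeats(g, 8, types=("palindromic",)),
                         "palindromic")
        pal_rc = as_triples(find_repeats(g_rc, 8, types=("palindromic",)),
                            "palindromic")
        pal_mirrored = {(n - (j + L), n - (i + L), L) for i, j, L in pal}
        assert pal_rc == pal_mirrored

    def test_monotone_in_min_len(self, rng):
        seq = random_seq(rng, 800)
        g = CircularGenome("m", seq)
        h8 = {(h.rtype, h.pos1.start, h.pos2.start, h.length)
              for h in find_repeats(g, 8)}
        h10 = {(h.rtype, h.pos1.start, h.pos2.start, h.length)
               for h in find_repeats(g, 10)}
        assert h10 <= h8

    def test_ir_pair_flagged_not_dropped(self, small_cohort):
        _, genome, _, truth, _ = small_cohort
        from plastocompare.quadripartite import detect_ir
        st = detect_ir(genome, min_ir_len=500)
        hits = find_repeats(genome, min_repeat_len=12, structure=st)
        ir_hits = [h for h in hits if h.is_ir_pair]
        assert len(ir_hits) == 1
        assert ir_hits[0].length == st.ir_length

    def test_deterministic_ordering(self, rng):
        seq = random_seq(rng, 500)
        g = CircularGenome("o", seq)
        h1 = find_repeats(g, 8)
        h2 = find_repeats(g, 8)
        assert h1 == h2
        keys = [(h.pos1.start, h.pos2.start, h.rtype) for h in h1]
        assert keys == sorted(keys)


class TestFindSSRs:
    def embed(self, rng, run):
        # flanks chosen so the run cannot extend
        left = "G" if run[0] != "G" else "C"
        right = "G" if run[-1] != "G" else "C"
        return random_seq(rng, 50, "CG") + left + run + right \
            + random_seq(rng, 50, "CG")

    def test_mono_threshold_boundary(self, rng):
        g10 = CircularGenome("a10", self.embed(rng, "A" * 10))
        hits = find_ssrs(g10)
        assert [(h.motif, h.unit, h.copies) for h in hits] == [("A", 1, 10)]
        g9 = CircularGenome("a9", self.embed(rng, "A" * 9))
        assert find_ssrs(g9) == []

    def test_dinucleotide_not_reported_as_tetra(self, rng):
        g = CircularGenome("at", self.embed(rng, "AT" * 6))
        hits = find_ssrs(g)
        assert len(hits) == 1
        h = hits[0]
        assert (h.motif, h.unit, h.copies) == ("AT", 2, 6)

    def test_partial_trailing_unit_not_counted(self, rng):
        g = CircularGenome("p", self.embed(rng, "CAT" * 5 + "CA"))
        hits = [h for h in find_ssrs(g) if h.unit == 3]
        assert len(hits) == 1 and hits[0].copies == 5

    def test_run_split_at_n(self, rng):
        seq = "G" * 20 + "A" * 11 + "N" + "A" * 11 + "G" * 20
        g = CircularGenome("n", seq)
        hits = [h for h in find_ssrs(g) if h.motif == "A"]
        assert [(h.locus.start, h.copies) for h in hits] == [(20, 11), (32, 11)]

    def test_canonical_motif_rotation(self, rng):
        g = CircularGenome("ta", self.embed(rng, "TA" * 6 + "T"))
        (h,) = find_ssrs(g)
        assert h.motif == "AT" and h.copies == 6

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed + 100)
        # AT-rich alphabet to make runs common
        seq = random_seq(rng, 3000, "AATC")
        g = CircularGenome("s", seq)
        got = {(h.locus.start, h.unit, h.copies) for h in find_ssrs(g)}
        assert got == ssr_oracle(seq, MIN_COPIES)

    def test_monotone_in_min_copies(self, rng):
        seq = random_seq(rng, 2000, "AAT")
        g = CircularGenome("m", seq)
        base = {(h.locus.start, h.unit) for h in find_ssrs(g)}
        stricter = {(h.locus.start, h.unit)
                    for h in find_ssrs(g, min_copies={1: 12, 2: 8, 3: 6})}
        assert stricter <= base


class TestSummary:
    def test_counts(self, small_cohort):
        _, genome, _, truth, _ = small_cohort
        summary = repeat_summary(truth.repeats, truth.ssrs)
        planted_by_type = {}
        for h in truth.repeats:
            planted_by_type[h.rtype] = planted_by_type.get(h.rtype, 0) + 1
        for t, c in planted_by_type.items():
            assert summary.repeat_counts[t] == c
        assert summary.total_ssrs == len(truth.ssrs)
        assert sum(summary.ssr_unit_counts.values()) == len(truth.ssrs)

    def test_empty(self):
        s = repeat_summary([], [])
        assert s.total_repeats == 0 and s.total_ssrs == 0
        assert all(v == 0 for v in s.repeat_counts.values())
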