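"""Alignment, VC/PIC counting, percentage statistics and marker ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_seq
from oracles import (alignment_score, exhaustive_pair_score, vc_pic_oracle)
from plastocompare.hotspot_stats import (align_locus, count_pic, count_vc,
                                         noncoding_coding_ratio, prealigned,
                                         round_half_up, select_markers,
                                         sliding_identity, variability_table)
from plastocompare.locus_extract import LocusDef, LocusSet

LD = LocusDef("toy", "noncoding", "LSC")


def make_set(seqs: dict) -> LocusSet:
    lens = [len(s) for s in seqs.values()]
    return LocusSet(LD, seqs, (min(lens), max(lens)))


class TestAlignLocus:
    def test_identical_sequences_gapless(self, rng):
        s = random_seq(rng, 120)
        aln = align_locus(make_set({"a": s, "b": s, "c": s}))
        assert aln.L == 120 and all("-" not in r for r in aln.rows.values())

    def test_single_gap_example(self):
        aln = align_locus(make_set({"a": "ACGT", "b": "AGT"}))
        assert aln.L == 4
        assert aln.rows["a"] == "ACGT" and aln.rows["b"].replace("-", "") == "AGT"
        assert aln.rows["b"].count("-") == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = random_seq(rng, 7), random_seq(rng, 6)
        aln = align_locus(make_set({"a": s1, "b": s2}))
        got = alignment_score(aln.rows["a"], aln.rows["b"])
        assert got == exhaustive_pair_score(s1, s2)

    def test_rows_reproduce_inputs(self, rng):
        seqs = {f"t{i}": random_seq(rng, 90 + int(i)) for i in range(5)}
        aln = align_locus(make_set(seqs))
        for t, row in aln.rows.items():
            assert row.replace("-", "") == seqs[t]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_locus(make_set({"a": "ACGT", "b": ""}))

    def test_prealigned_validation(self):
        with pytest.raises(ValueError, match="unequal"):
            prealigned(LD, {"a": "ACGT", "b": "AC-"})
        aln = prealigned(LD, {"a": "ACGT", "b": "AC-T"})
        assert aln.L == 4


class TestCounting:
    def test_definitional_columns(self):
        aln = prealigned(LD, {"1": "AAA", "2": "AC-", "3": "-AN", "4": "AAA"})
        # col0 {A,A,-,A}: not variable; col1 {A,C,A,A}: variable, not PIC;
        # col2 {A,-,N,A}: gaps/N carry no state -> not variable
        assert count_vc(aln) == 1
        assert count_pic(aln) == 0

    def test_pic_requires_two_doubly_present_states(self):
        assert count_pic(prealigned(LD, {"1": "A", "2": "A", "3": "C",
                                         "4": "C"})) == 1
        assert count_pic(prealigned(LD, {"1": "A", "2": "A", "3": "A",
                                         "4": "C"})) == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        L = int(rng.integers(1, 60))
        rows = {f"t{i}": random_seq(rng, L, "ACGTN-") for i in range(k)}
        aln = prealigned(LD, rows)
        evc, epic = vc_pic_oracle(list(rows.values()))
        assert count_vc(aln) == evc
        assert count_pic(aln) == epic
        assert count_pic(aln) <= count_vc(aln) <= aln.L


class TestVariabilityTable:
    def make_alignments(self, rng):
        alns = []
        for i, (lclass, rate) in enumerate([("coding", 0.02),
                                            ("coding", 0.05),
                                            ("noncoding", 0.08),
                                            ("noncoding", 0.12)]):
            ld = LocusDef(f"loc{i}", lclass, "LSC")
            base = random_seq(rng, 300)
            rows = {}
            for t in range(4):
                arr = list(base)
                for p in np.flatnonzero(rng.random(300) < rate):
                    arr[p] = "ACGT"[(("ACGT".index(arr[p])) + 1) % 4]
                rows[f"t{t}"] = "".join(arr)
            alns.append(prealigned(ld, rows))
        return alns

    def test_formula_invariant(self, rng):
        res = variability_table(self.make_alignments(rng))
        for _, r in res.records.iterrows():
            assert r["pct_vc"] == round_half_up(100 * r["n_vc"]
                                                / r["aligned_length"], 2)
            assert r["pct_pic"] == round_half_up(100 * r["n_pic"]
                                                 / r["aligned_length"], 2)
            assert r["n_pic"] <= r["n_vc"] <= r["aligned_length"]

    def test_class_summary_and_ratio(self, rng):
        res = variability_table(self.make_alignments(rng))
        summary = res.class_summary.set_index("class")
        assert set(summary.index) == {"coding", "noncoding"}
        assert res.noncoding_coding_ratio == round_half_up(
            summary.loc["noncoding", "mean_pct_vc"]
            / summary.loc["coding", "mean_pct_vc"], 1)

    def test_published_style_rounding(self):
        assert round_half_up(100 * 276 / 1177, 2) == 23.45
        assert round_half_up(100 * 139 / 1177, 2) == 11.81
        assert noncoding_coding_ratio(12.33, 6.50) == 1.9


class TestSelectMarkers:
    def make_records(self):
        rows = []
        for i, (name, vc, pic) in enumerate([
                ("a", 20.0, 8.0), ("b", 15.0, 9.0), ("c", 15.0, 9.0),
                ("d", 15.0, 7.0), ("e", 10.0, 2.0)]):
            rows.append({"locus": name, "class": "noncoding", "region": "LSC",
                         "length_min": 100, "length_max": 120,
                         "aligned_length": 130, "n_vc": int(vc),
                         "pct_vc": vc, "n_pic": int(pic), "pct_pic": pic})
        rows.append({"locus": "gene", "class": "coding", "region": "LSC",
                     "length_min": 100, "length_max": 100,
                     "aligned_length": 100, "n_vc": 30, "pct_vc": 30.0,
                     "n_pic": 10, "pct_pic": 10.0})
        return pd.DataFrame(rows)

    def test_ranking_and_tiebreak(self):
        out = select_markers(self.make_records(), top_n=4)
        assert list(out["locus"]) == ["a", "b", "c", "d"]  # pic desc, name asc
        assert "gene" not in set(out["locus"])  # coding excluded

    def test_permutation_stability(self):
        rec = self.make_records()
        shuffled = rec.sample(frac=1, random_state=7).reset_index(drop=True)
        assert select_markers(rec, top_n=3).equals(
            select_markers(shuffled, top_n=3))

    def test_min_pct_threshold(self):
        out = select_markers(self.make_records(), top_n=None, min_pct_vc=14.0)
        assert len(out) == 4

    def test_top_n_larger_than_available(self):
        out = select_markers(self.make_records(), top_n=50)
        assert len(out) == 5


class TestSlidingIdentity:
    def test_identical_rows_all_100(self, rng):
        s = random_seq(rng, 400)
        prof = sliding_identity({"ref": s, "x": s}, "ref")
        assert (prof["identity"] == 100.0).all()

    def test_five_mismatches_in_window(self, rng):
        s = random_seq(rng, 100)
        other = list(s)
        for p in (10, 20, 30, 40, 50):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        prof = sliding_identity({"ref": s, "x": "".join(other)}, "ref",
                                window=100, step=100)
        assert list(prof["identity"]) == [95.0]

    def test_window_validation(self, rng):
        s = random_seq(rng, 200)
        with pytest.raises(ValueError):
            sliding_identity({"ref": s, "x": s}, "ref", window=20, step=30)
        with pytest.raises(ValueError):
            sliding_identity({"ref": s, "x": s}, "ref", window=5, step=5)

    def test_sparse_window_is_nan(self):
        ref = "A" * 5 + "-" * 95
        row = "A" * 5 + "-" * 95
        prof = sliding_identity({"ref": ref + ref, "x": row + row}, "ref",
                                window=100, step=100)
        assert np.isnan(prof["identity"]).all()

    def test_profile_mean_close_to_global_identity(self, rng):
        s = random_seq(rng, 2000)
        other = list(s)
        flips = np.flatnonzero(rng.random(2000) < 0.05)
        for p in flips:
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        other = "".join(other)
        prof = sliding_identity({"ref": s, "x": other}, "ref",
                                window=100, step=25)
        global_ident = 100 * sum(a == b for a, b in zip(s, other)) / 2000
        assert abs(prof["identity"].mean() - global_ident) < 1.0
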