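"""Generator ground truth, ledger fidelity, evolution and pipeline closure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import pandas as pd
from oracles import expected_pct_variable
from plastocompare.hotspot_stats import align_locus, variability_table
from plastocompare.locus_extract import collect_homologs, extract_loci
from plastocompare.plastome_io import revcomp
from plastocompare.quadripartite import compare_junctions, detect_ir, junction_report
from plastocompare.repeat_scan import find_repeats, find_ssrs
from plastocompare.synthetic_data import (SyntheticPlan, build_plan,
                                          generate_ancestor, generate_cohort,
                                          small_plan)


def overlaps_any(iv, intervals):
    return any(s < iv.end and iv.start < e for s, e in intervals)


class TestPlanValidation:
    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            small_plan(0, coding_rate_range=(0.0, 0.9))
        with pytest.raises(ValueError):
            small_plan(0, background_rate=0.8)

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            SyntheticPlan(seed=0, lsc_len=1000, ssc_len=2000, ir_len=500)

    def test_colliding_planted_elements_rejected(self):
        from plastocompare.synthetic_data import PlantedSSR
        plan = small_plan(0)
        clash = (PlantedSSR("A", 12, "LSC", 600),
                 PlantedSSR("T", 12, "LSC", 605))
        plan2 = SyntheticPlan(**{**plan.__dict__, "planted_ssrs": clash})
        with pytest.raises(ValueError, match="collide"):
            generate_ancestor(plan2)


class TestAncestor:
    def test_construction_invariants(self, small_cohort):
        plan, genome, features, truth, _ = small_cohort
        assert genome.length == plan.genome_length
        l, r, s = plan.lsc_len, plan.ir_len, plan.ssc_len
        irb = genome.seq[l : l + r]
        ira = genome.seq[l + r + s :]
        assert irb == revcomp(ira)

    def test_seed_reproducibility(self):
        g1, f1, t1 = generate_ancestor(small_plan(17))
        g2, f2, t2 = generate_ancestor(small_plan(17))
        assert g1.seq == g2.seq and f1 == f2
        g3, _, _ = generate_ancestor(small_plan(18))
        assert g3.seq != g1.seq

    def test_junction_recovery_exact(self, small_cohort):
        _, genome, features, truth, _ = small_cohort
        st = detect_ir(genome, min_ir_len=500)
        assert st.junctions() == truth.junctions
        assert {"LSC": st.lsc_length, "IRb": st.ir_length,
                "SSC": st.ssc_length, "IRa": st.ir_length} == \
            truth.region_lengths

    def test_junction_gene_truth_reproduced(self, small_cohort):
        _, genome, features, truth, _ = small_cohort
        st = detect_ir(genome, min_ir_len=500)
        got = {(r.junction, r.gene, r.relation, r.distance)
               for r in junction_report(st, features)}
        expected = {(r.junction, r.gene, r.relation, r.distance)
                    for r in truth.junction_genes}
        assert expected == got

    def test_ssr_ledger_fidelity(self, small_cohort):
        _, genome, _, truth, _ = small_cohort
        found = find_ssrs(genome)
        planted = {(s.locus.start, s.unit, s.copies) for s in truth.ssrs}
        got = {(s.locus.start, s.unit, s.copies) for s in found}
        assert planted <= got
        for s in found:
            if (s.locus.start, s.unit, s.copies) not in planted:
                assert overlaps_any(s.locus, truth.planted_intervals)

    def test_repeat_ledger_fidelity(self, small_cohort):
        _, genome, _, truth, _ = small_cohort
        st = detect_ir(genome, min_ir_len=500)
        found = [h for h in find_repeats(genome, min_repeat_len=12,
                                         structure=st) if not h.is_ir_pair]
        planted = {(h.rtype, h.pos1.start, h.pos2.start, h.length)
                   for h in truth.repeats}
        got = {(h.rtype, h.pos1.start, h.pos2.start, h.length) for h in found}
        assert planted <= got
        for h in found:
            key = (h.rtype, h.pos1.start, h.pos2.start, h.length)
            if key not in planted:
                assert overlaps_any(h.pos1, truth.planted_intervals) or \
                    overlaps_any(h.pos2, truth.planted_intervals)


class TestEvolution:
    def test_zero_rate_gives_identical_taxa(self):
        plan = small_plan(5, taxa=3, coding_rate_range=(0.0, 0.0),
                          noncoding_rate_range=(0.0, 0.0),
                          background_rate=0.0)
        genome, _, _, taxa = generate_cohort(plan)
        assert {g.seq for g, _ in taxa} == {genome.seq}

    def test_ir_invariant_preserved(self, small_cohort):
        plan, _, _, _, taxa = small_cohort
        l, r, s = plan.lsc_len, plan.ir_len, plan.ssc_len
        for g, _ in taxa:
            assert g.seq[l : l + r] == revcomp(g.seq[l + r + s :])

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            small_plan(0, locus_rates={"lsg01": 0.8})

    def test_junction_shift_creates_new_ir_type(self):
        plan = small_plan(11, taxa=3, junction_shifts={"t03": 350})
        _, _, _, taxa = generate_cohort(plan)
        items = [(g.id, detect_ir(g, min_ir_len=500), f) for g, f in taxa]
        _, genomes = compare_junctions(items)
        by_id = genomes.set_index("genome")
        assert by_id.loc["t03", "ir_type"] != by_id.loc["t01", "ir_type"]
        assert by_id.loc["t03", "ir_length"] == by_id.loc["t01",
                                                          "ir_length"] + 350

    def test_junction_contraction(self):
        plan = small_plan(11, taxa=2, junction_shifts={"t02": -250})
        _, _, _, taxa = generate_cohort(plan)
        by_id = {g.id: g for g, _ in taxa}
        assert by_id["t02"].length == by_id["t01"].length - 250
        st = detect_ir(by_id["t02"], min_ir_len=500)
        assert st.ir_length == plan.ir_len - 250

    def test_supplied_tree_taxa(self):
        nwk = "((x:0.5,y:0.5):0.5,z:1.0);"
        plan = small_plan(6, taxa=3, tree_newick=nwk)
        _, _, truth, taxa = generate_cohort(plan)
        assert sorted(g.id for g, _ in taxa) == ["x", "y", "z"]
        assert truth.tree_newick == nwk


class TestPipelineClosure:
    def test_generate_extract_align_rank(self):
        """Full closure: recovered per-locus variability ranks the planted
        rates (Spearman) on a medium-size cohort."""
        plan = build_plan(31, lsc_len=16000, ssc_len=1600, ir_len=2500,
                          taxa=8, n_lsc_genes=10, n_ssc_genes=1,
                          n_mono_ssrs=3, n_di_ssrs=1, n_tri_ssrs=1,
                          n_forward=2, n_palindromic=1, n_reverse=1,
                          n_complement=1,
                          coding_rate_range=(0.005, 0.10),
                          noncoding_rate_range=(0.005, 0.10))
        _, _, truth, taxa = generate_cohort(plan)
        per_taxon = {}
        for g, f in taxa:
            st = detect_ir(g, min_ir_len=500)
            loci, _ = extract_loci(g, f, st, min_len=100)
            per_taxon[g.id] = loci
        sets = collect_homologs(per_taxon)
        alns = [align_locus(ls) for ls in sets]
        res = variability_table(alns)
        merged = res.records.merge(
            pd.DataFrame([{"locus": k, "rate": v}
                          for k, v in truth.locus_rates.items()]), on="locus")
        assert len(merged) >= 20
        rho = spearmanr(merged["rate"], merged["pct_vc"]).statistic
        assert rho >= 0.9

    def test_variability_matches_star_tree_expectation(self):
        """Observed mean percent-variable at a fixed rate sits within
        3 standard errors of the closed-form star-tree expectation."""
        rate = 0.03
        plan = build_plan(13, lsc_len=16000, ssc_len=1600, ir_len=2500,
                          taxa=8, n_lsc_genes=10, n_ssc_genes=1,
                          n_mono_ssrs=3, n_di_ssrs=1, n_tri_ssrs=1,
                          n_forward=2, n_palindromic=1, n_reverse=1,
                          n_complement=1,
                          coding_rate_range=(rate, rate),
                          noncoding_rate_range=(rate, rate),
                          background_rate=rate)
        _, _, truth, taxa = generate_cohort(plan)
        per_taxon = {}
        for g, f in taxa:
            st = detect_ir(g, min_ir_len=500)
            loci, _ = extract_loci(g, f, st, min_len=100)
            per_taxon[g.id] = loci
        sets = collect_homologs(per_taxon)
        res = variability_table([align_locus(ls) for ls in sets])
        vals = res.records["pct_vc"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        expected = expected_pct_variable(rate, plan.taxa)
        assert abs(vals.mean() - expected) <= 3 * max(se, 0.05)
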