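# plastocompare

Comparative analysis of chloroplast (plastid) genomes: quadripartite
structure and inverted-repeat (IR) junction comparison, dispersed-repeat and
microsatellite (SSR) censuses, extraction of homologous coding and
non-coding loci, and per-locus mutation-hotspot statistics for molecular
marker mining.

## The problem

A typical land-plant plastome is a ~130–160 kb circle with a quadripartite
organisation: a large and a small single-copy region (LSC, SSC) separated by
two identical inverted-repeat copies (IRb = reverse complement of IRa).  The
four junctions — JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA
(IRa/LSC) — shift over evolutionary time as the IR expands or contracts,
moving genes such as *rps19*, *ndhF*, *ndhH* and *trnH* between single-copy
and duplicated territory.  At the same time, nucleotide divergence is highly
heterogeneous along the molecule: intergenic spacers and introns accumulate
substitutions much faster than exons, and the fastest non-coding loci make
good phylogenetic markers.  This package provides the full toolchain used in
comparative plastome papers to quantify both phenomena, plus a synthetic
plastome simulator so every stage can be validated against known ground
truth.

## The statistics at the core

For each homologous locus aligned across *k* taxa (aligned length *L*,
columns over `{A,C,G,T,N,-}`):

* **NS**, the number of *variable characters* (VCs): columns with ≥ 2
  distinct bases among `{A,C,G,T}` — gaps and N carry no character state;
* **percent VCs** = (NS / L) × 100, rounded half-up to two decimals;
* **PICs**, *parsimony-informative characters*: columns with ≥ 2 states each
  present in ≥ 2 rows, and **percent PICs** = (PIC / L) × 100;
* per-class (coding vs non-coding) means of percent VCs and their ratio.

Marker candidates are the non-coding loci ranked by percent VCs (ties broken
by percent PICs, then name).

Around these sit the structural analyses: exact maximal inverted-repeat
detection by seed-and-extend on the doubled circular sequence; REPuter-style
maximal dispersed repeats of the four types (forward, palindromic, reverse,
complement; default minimum length 8 bp); and MISA-style SSR detection
(maximal tandem arrays of a primitive 1–6 bp motif with minimum copy numbers
10/6/5/5/5/5 for mono- through hexanucleotides).

## Worked example

Generate a small synthetic cohort (LSC 5 kb, IR 2 kb, SSC 1 kb, four taxa),
detect the structure of one genome, and mine hotspot loci across the cohort:

```python
from plastocompare import *
from plastocompare.locus_extract import collect_homologs, extract_loci
from plastocompare.hotspot_stats import align_locus, variability_table, select_markers
from plastocompare.synthetic_data import small_plan, generate_cohort

plan = small_plan(1, taxa=4)
ancestor, features, truth, taxa = generate_cohort(plan)

g, f = taxa[0]
st = detect_ir(g, min_ir_len=500)
print(f"{g.id}: LSC={st.lsc_length}  IR={st.ir_length}  SSC={st.ssc_length}")
for r in junction_report(st, f):
    print(f"  {r.junction}: {r.gene} ({r.relation}, {r.distance} bp)")

per_taxon = {}
for tg, tf in taxa:
    stx = detect_ir(tg, min_ir_len=500)
    loci, _ = extract_loci(tg, tf, stx, min_len=100)
    per_taxon[tg.id] = loci
res = variability_table([align_locus(s) for s in collect_homologs(per_taxon)])
print(res.class_summary.to_string(index=False))
```

which prints

```
t01: LSC=5000  IR=2000  SSC=1000
  JLB: rps19 (spans, 0 bp)
  JSB: ndhF (spans, 0 bp)
  JSA: ndhH (spans, 0 bp)
  JLA: trnH (upstream, 30 bp)
  JLA: psbA (downstream, 80 bp)
    class  n_loci  min_pct_vc  max_pct_vc  mean_pct_vc
   coding       9        0.70        3.68         2.49
noncoding       9        0.91        6.88         3.03
```

The structure detector recovers the planted region lengths exactly; *rps19*,
*ndhF* and *ndhH* straddle their junctions as planted, *psbA* sits 80 bp
downstream of JLA, and the non-coding loci are on average more variable than
the coding ones (here both classes were simulated at modest rates; with
realistic rate separation the class-mean ratio approaches the ~1.9×
published for herbaceous-bamboo plastomes).

The same pipeline is scriptable from the shell:

```bash
plastocompare synth --seed 1 --scale small --taxa 4 -o cohort/
plastocompare quadripartite cohort/t01.fasta --gff cohort/t01.gff3 --min-ir-len 500
plastocompare ssrs cohort/t01.fasta
plastocompare run --config run.yaml     # full artifact bundle + manifest
```

## Layout

| module | contents |
| --- | --- |
| `plastome_io` | FASTA/GFF3/feature-table I/O, circular intervals, revcomp |
| `quadripartite` | IR detection, canonical orientation, junction reports |
| `repeat_scan` | maximal dispersed repeats (4 types) and SSRs |
| `locus_extract` | coding/intron/spacer partitioning, homolog collection |
| `hotspot_stats` | center-star alignment, VC/PIC statistics, marker ranking, sliding identity |
| `synthetic_data` | plastome simulator with ground-truth ledger |
| `reports` / `cli` | end-to-end pipeline, artifact bundle, `plastocompare` CLI |
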