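# Methods

This note documents the models, conventions and numerical choices behind
plastocompare, in the spirit of a methods appendix: what each stage computes,
which knobs matter, what the simulator does and does not emulate, and where
design decisions were genuinely open.

## Coordinates and canonical orientation

All internal coordinates are 0-based half-open; file I/O (GFF3 and the
feature-table TSV dialect) converts from/to the 1-based inclusive convention
at the boundary, and all report output is 1-based.  Circular features are
represented by a single interval with a `wraps` flag rather than split
parts; spans are computed modulo genome length.  IUPAC ambiguity codes other
than N are normalized to N on input (with a logged count): every downstream
statistic treats only unambiguous bases, so keeping the original codes would
only complicate column-state bookkeeping without changing any result.

Genomes are reported in a canonical orientation — rotated so the LSC starts
at the origin, flipped so psbA/trnH fall in the first half of the LSC when
annotated (lexicographically smaller LSC string otherwise).  This makes
junction tables, spacer names and rerun artifacts comparable across inputs
and across runs.

## Inverted-repeat detection

`detect_ir` finds the maximal-length *exact* inverted-repeat pair by
seed-and-extend: k-mer seeds (default 25 bp, clipped to the minimum IR
length) are matched between the doubled sequence and its reverse complement,
so origin-crossing IR copies need no special casing; each seed is extended
to a maximal run along its anti-diagonal.  The two single-copy arcs between
the copies are labelled by span alone (longer = LSC) — no annotation needed,
and ties are a structural error rather than a silent guess.  Published
plastome IR copies are near-identical, and no mismatch tolerance is defined
by the analyses this package reproduces, so the IR identity invariant
(IRb == revcomp(IRa)) is asserted exactly; genomes with no pair at the
minimum length (cf. conifer plastomes that lost one IR) raise a structured
error, and several non-identical pairs tying for maximal length raise an
error listing the candidates.

Junction *J* between regions X and Y is the coordinate of the first base of
Y.  A gene **spans** a junction only when it covers bases on both sides
(i.e. contains both J and J−1); a gene whose boundary coincides with the
junction is upstream/downstream at distance 0.  Distances are measured from
the gene's *nearest* end to the junction — the common plotting convention;
measuring to the gene start instead would only relabel the same geometry.
Genomes are classified into "IR types" by the identity+relation of the genes
at JSB and JSA, which is exactly the feature that distinguishes published
junction architectures (e.g. *ndhF* straddling JSB versus lying wholly in
the SSC).

## Dispersed repeats

Four copy relations are scanned: forward (identical), palindromic (reverse
complement), reverse (reversed) and complement (complemented).  A hit is
*maximal* — extension on either side in the type-preserving direction fails —
and sub-hits of longer hits are therefore never reported.  Copies may
overlap; the two copies must be distinct; positions containing N never
participate.  Detection is seed-and-extend over exact k-mer matches
(k = min(12, minimum length)); forward/complement runs live on diagonals,
palindromic/reverse runs on anti-diagonals, where mirror-image and
self-mirror runs are deduplicated by the run-center criterion.  The default
minimum length is 8 bp, read from the "motif length > 8 bp" convention of
REPuter-style censuses as an inclusive minimum and exposed as a parameter;
published repeat totals are version- and convention-dependent, so counts are
validated against a brute-force oracle on random sequences rather than
against any printed total.  When a quadripartite structure is supplied, the
genome-scale IRa-vs-IRb palindromic hit is flagged `is_ir_pair` (not
dropped), so whole-genome censuses can include or exclude it explicitly.
Both IR copies are scanned; SSRs and repeats inside the IR are hence counted
twice unless the caller deduplicates, mirroring a plain whole-genome scan.

## SSRs

An SSR is a maximal tandem array of a primitive (aperiodic) 1–6 bp motif.
For unit size u, positions x with seq[x] == seq[x+u] (both unambiguous) form
match runs; a maximal run of r such positions is an array of r+u characters
and floor((r+u)/u) complete copies.  Partial trailing units do not count and
the reported locus covers whole copies only; arrays containing N split at
the N.  Minimum copies are 10/6/5/5/5/5 for units 1–6 — the standard
MISA-style thresholds.  The motif is reported as its lexicographically
minimal rotation; requiring primitivity prevents a dinucleotide array from
re-surfacing as a tetranucleotide.  Adjacent/interrupted arrays are reported
as separate simple runs (no compound merging): the simplest well-defined
behaviour, and a documented divergence from MISA's compound annotation.

## Locus extraction

Coding loci are the concatenated exon parts of each CDS/tRNA/rRNA feature
(reverse-complemented for minus-strand genes); non-coding loci are the
introns (gaps between exon parts of one gene, named "<gene> intron") and the
intergenic spacers (gaps between consecutive feature envelopes, named
"<geneA>-<geneB>" in canonical orientation order — flanking features of any
class bound a spacer, matching conventional spacer names that mix gene
classes).  Only one IR copy (IRa) contributes loci, so duplicated genes are
counted once; overlapping genes contribute the overlap to both coding loci
and to no spacer (logged); features marked pseudo still bound spacers and
still yield (flagged) coding loci, since variability is routinely computed
for pseudogenized genes.  The length filter is strict: loci of length
> 100 bp (default) are kept, 100 bp exactly is discarded.  A coverage
account is kept over LSC+SSC+IRa: every base is assigned to a locus or to a
logged residual (short-locus/overlap/unannotated) set, and
assigned + residual equals the scope size by construction — an invariant the
tests assert.  Homologs are matched across taxa *by locus name only*
(annotation-based homology); loci absent from any taxon are excluded from
statistics by default (`min_taxa`), a policy choice the caller can relax.

## Alignment and variability statistics

Loci are aligned with a deterministic center-star multiple alignment: the
center is the sequence with the highest summed pairwise alignment score
(ties: lexicographically first taxon); every other sequence is globally
aligned to the center with affine gaps (match 1, mismatch −1, gap open −4,
gap extend −1, the open score charged to the first gapped position) using
Biopython's PairwiseAligner for the pairwise DP; the pairwise alignments are
merged under the maximal per-position gap profile ("once a gap, always a
gap").  A deterministic re-implementable aligner was preferred over an
external MSA tool because the contribution being reproduced is the
*statistics*, not the aligner; a pre-aligned FASTA path (validated, used
as-is) is the fidelity escape hatch when a reference alignment exists.

On an alignment with rows over {A,C,G,T,N,-} and aligned length L (gap
columns included, per the "aligned sequence length" convention):

* NS = columns with ≥ 2 distinct bases among {A,C,G,T}; gap- or N-only
  variation does not count;
* PIC = columns with ≥ 2 such states each in ≥ 2 rows;
* percent VCs = 100·NS/L and percent PICs = 100·PIC/L, rounded **half-up**
  to 2 decimals (printed-table convention; Python's bankers' rounding would
  disagree on exact ties);
* class summaries use the unweighted mean over loci (not length-weighted),
  which is how published class means of per-locus percentages behave; the
  non-coding/coding ratio of the (2-decimal) class means is reported to one
  decimal, half-up.

Markers are the non-coding records sorted by percent VCs descending, ties by
percent PICs then name — a permutation-stable top-N.

Sliding-window identity profiles (default window 100, step 25) compare each
row of a whole-genome alignment to a chosen reference: identity =
100 × matches / positions where both rows have a base; windows with < 10
comparable positions yield NaN.  In the pipeline, equal-length genomes are
compared positionally; unequal-length inputs are aligned with MAFFT when
available.

## The synthetic-data generator

`synthetic_data` builds plastomes with *known* structure so that every stage
is testable without downloads.  The default plan mirrors the published
herbaceous-bamboo dimensions — LSC 82,935 bp, SSC 12,984 bp, IR 19,993 bp,
GC 0.387, 13 taxa — with junction genes at realistic offsets (*rps19*
spanning JLB, *ndhF* spanning JSB, *ndhH* spanning JSA, *psbA* 80 bp
downstream of JLA, *trnH* inside the IR ending 30 bp short of JLA), filler
genes (some with introns) spread through the LSC/SSC, 14 mono-, 1 di- and
1 trinucleotide SSRs, and 10/6/3/2 forward/palindromic/reverse/complement
dispersed repeats — the qualitative shape of published censuses.  Everything
scales down (tests use LSC 5 kb / IR 2 kb / SSC 1 kb, the simulations use an
intermediate ~40 kb scale) so the suite and the acceptance script run in
minutes on one CPU; the statistical machinery is size-independent.

Construction details that matter for exactness:

* IRb is written as revcomp(IRa) and every subsequent edit inside either IR
  copy is mirrored, so the IR identity holds at tolerance 0 by construction
  and after evolution.
* Planted SSRs/repeats get *guard bases* at their flanks chosen to defeat
  every extension rule, so each planted element is recovered as exactly its
  planted maximal hit.
* Accidental background repeats ≥ 12 bp and accidental SSRs are screened
  out by point edits; hits that touch planted intervals are left alone
  (they are consequences of the planted elements — a poly-A run *is* a
  period-1 forward repeat, a poly-A next to a poly-T *is* a palindromic
  pair) and the ground-truth ledger records the planted intervals so tests
  can distinguish planted, secondary and unexplained hits.  Planted SSRs
  and repeats are restricted to the single-copy regions to keep the ledger
  one-to-one (an IR-planted element would appear twice).
* Evolution applies Jukes–Cantor substitutions independently per site along
  each branch of a star tree (or a supplied newick): per-branch per-site
  substitution probability = locus rate × branch length, capped below 0.75,
  substituting to one of the three other bases uniformly.  No indels by
  default, so locus homology stays positional, synthetic "alignments" are
  exact, and the probability that a column is variable has the closed form
  1 − (1−p)^k − 3·(p/3)^k used as the simulation oracle.  This separates
  statistic error from aligner error by design.
* Default locus rates are drawn uniformly per locus: coding 0.001–0.010,
  non-coding 0.002–0.018.  With 13 taxa these give class means of roughly
  6–7% and ~12% variable characters — the published order of magnitude —
  and a class-mean ratio near 1.9.
* Optional per-taxon junction shifts move JSB by ±d bases as a true IR
  expansion (duplicating the absorbed SSC prefix into IRa) or contraction
  (releasing IRb tail into single copy and deleting its IRa mirror),
  remapping feature coordinates, to create divergent IR architectures.

What the simulator does **not** emulate: indel mutational processes (an
aligner-exercising indel mode exists but is excluded from recovery tests),
rate variation within a locus, base-compositional heterogeneity,
recombination or gene conversion beyond perfect IR mirroring, pseudogene
ORF decay, and sequencing/assembly error.  Passing tests therefore
demonstrate correctness of the *measurements* under a clean substitution
model, not robustness to alignment ambiguity or annotation error in real
data.

## Numerical and degenerate-input conventions

Half-up decimal rounding everywhere a printed-style percentage is produced;
deterministic tie-breaks (lexicographic) for center choice, marker ranking
and junction gene listing; empty annotation gives an empty junction report;
an empty sequence in a locus set, unequal pre-aligned rows, a window
smaller than the step (or than 10 columns), min repeat length < 2, and
substitution rates outside [0, 0.75) are all hard errors.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; no
global RNG state is touched, and fixed seeds give byte-identical genomes and
artifacts.

## Pipeline reports

`run_compare` writes the artifact bundle (genome summary, repeat and SSR
censuses, junction comparison, variability table, marker table, identity
profile, concatenated marker matrix) plus a JSON manifest with a SHA-256
checksum per file; reruns under the same config and inputs are
byte-identical, and any stage failure removes partial outputs.  GC% is
(G+C)/(A+C+G+T).  Gene counts are reported both total and unique (IR
duplicates collapse in the latter), and because the definition of "coding
fraction" varies between reports, both a CDS-only and a CDS+tRNA+rRNA
variant are emitted without claiming either as canonical.

## Known limitations

Homology is name-based, so inconsistent annotation vocabularies across
genomes fragment locus sets; the center-star aligner is O(k²) in pairwise
scores and not intended for whole-genome alignment (equal-length or MAFFT
paths cover that); dispersed-repeat scanning is linear in sequence but
quadratic in low-complexity seed collisions; repeats/SSRs crossing the
origin of the linearised circle are not reported (both scanners are linear
scans, matching common practice); and junction shifts are implemented at JSB
only, which suffices to generate distinct IR architectures.
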