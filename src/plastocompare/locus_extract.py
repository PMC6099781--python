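"""Partition an annotated plastome into homologous coding / non-coding loci.

Coding loci are the concatenated exons of each CDS/tRNA/rRNA feature.
Non-coding loci are the introns (gaps between exon parts of one gene) and the
intergenic spacers (gaps between consecutive feature envelopes along the
genome), named ``<geneA>-<geneB>`` in canonical orientation order.  Only one
IR copy (IRa) contributes loci, so duplicated genes are counted once; loci
whose (unaligned) length is <= ``min_len`` are discarded.  Overlapping genes
contribute the overlap to both coding loci and to no spacer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .plastome_io import (CircularGenome, GeneFeature, Interval, revcomp)
from .quadripartite import QuadripartiteStructure, canonicalize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusDef:
    name: str
    lclass: str  # coding | noncoding
    region: str  # LSC | SSC | IR

    def __post_init__(self) -> None:
        if self.lclass not in ("coding", "noncoding"):
            raise ValueError(f"bad locus class {self.lclass!r}")


@dataclass(frozen=True)
class ExtractedLocus:
    locus: LocusDef
    seq: str
    segments: tuple[Interval, ...]  # genome intervals composing the locus
    pseudo: bool = False


@dataclass
class ExtractionReport:
    """Bookkeeping for the coverage invariant over LSC + SSC + IRa."""

    scope_bases: int = 0
    assigned_bases: int = 0  # covered by at least one kept locus
    residual_bases: int = 0  # discarded short loci, overlaps outside loci, gaps
    n_discarded_short: int = 0
    n_overlap_bases: int = 0


@dataclass(frozen=True)
class LocusSet:
    """One homologous locus across taxa (input to the alignment stage)."""

    locus: LocusDef
    seqs: Mapping[str, str]  # taxon -> unaligned sequence
    length_range: tuple[int, int]


def _region_label(structure: QuadripartiteStructure, iv: Interval) -> str:
    # majority vote by the midpoint of the interval (loci are small relative
    # to regions, so boundary-straddling loci are labelled by their bulk)
    n = structure.genome_length
    mid = (iv.start + iv.span(n) // 2) % n
    region = structure.region_of(mid)
    return "IR" if region in ("IRa", "IRb") else region


def extract_loci(genome: CircularGenome, features: Sequence[GeneFeature],
                 structure: QuadripartiteStructure | None = None,
                 min_len: int = 100, ir_copies: str = "one",
                 ) -> tuple[list[ExtractedLocus], ExtractionReport]:
    """Extract coding and non-coding loci from one annotated genome.

    The genome is first put in canonical orientation (LSC starting at 0) so
    locus names and spacer order are comparable across taxa.  ``min_len`` is
    a strict threshold: loci of exactly ``min_len`` bases are discarded.
    """
    if ir_copies not in ("one", "both"):
        raise ValueError("ir_copies must be 'one' or 'both'")
    genome, feats, structure = canonicalize(genome, features, structure)
    n = genome.length
    a = structure.lsc_length
    b = a + structure.ir_length  # IRb end / SSC start
    c = b + structure.ssc_length  # SSC end / IRa start

    def in_irb(iv: Interval) -> bool:
        return not iv.wraps and a <= iv.start and iv.end <= b

    # scope mask: 0 unassigned, 1 feature, 2 spacer, 3 residual
    scope = np.zeros(n, dtype=np.int8)
    scope_sel = np.ones(n, dtype=bool)
    if ir_copies == "one":
        scope_sel[a:b] = False

    loci: list[ExtractedLocus] = []
    report = ExtractionReport(scope_bases=int(scope_sel.sum()))

    def mark(iv: Interval, code: int) -> None:
        if iv.wraps:
            scope[iv.start:] = np.maximum(scope[iv.start:], code)
            scope[: iv.end] = np.maximum(scope[: iv.end], code)
        else:
            scope[iv.start : iv.end] = np.maximum(scope[iv.start : iv.end], code)

    def keep_or_discard(locus: LocusDef, seq: str, segs: tuple[Interval, ...],
                        pseudo: bool = False) -> None:
        if len(seq) > min_len:
            loci.append(ExtractedLocus(locus, seq, segs, pseudo))
            for s in segs:
                mark(s, 1 if locus.lclass == "coding" else 2)
        else:
            report.n_discarded_short += 1
            logger.info("%s: locus %s discarded (%d bp <= %d)", genome.id,
                        locus.name, len(seq), min_len)
            for s in segs:
                mark(s, 3)

    # order features along the canonical genome; skip IRb copies
    usable = [f for f in feats
              if not (ir_copies == "one" and in_irb(f.envelope(n)))]
    usable.sort(key=lambda f: (f.envelope(n).start, f.envelope(n).end, f.name))

    names_seen: dict[str, int] = {}
    for f in usable:
        # coding locus: exon parts joined, reported on the feature's strand
        exon_seq = "".join(genome.fragment(p) for p in f.parts)
        if f.strand == "-":
            exon_seq = revcomp(exon_seq)
        name = f.name
        if name in names_seen:
            names_seen[name] += 1
            name = f"{name}.{names_seen[f.name]}"
        else:
            names_seen[name] = 1
        region = _region_label(structure, f.envelope(n))
        keep_or_discard(LocusDef(name, "coding", region), exon_seq, f.parts,
                        f.pseudo)
        # introns between consecutive exon parts
        if len(f.parts) > 1:
            n_introns = len(f.parts) - 1
            for idx in range(n_introns):
                gap = Interval(f.parts[idx].end, f.parts[idx + 1].start)
                if gap.end <= gap.start:
                    continue
                iname = (f"{f.name} intron" if n_introns == 1
                         else f"{f.name} intron {idx + 1}")
                keep_or_discard(LocusDef(iname, "noncoding",
                                         _region_label(structure, gap)),
                                genome.fragment(gap), (gap,))

    # intergenic spacers between consecutive envelopes, clipped to scope
    envs = [(f.envelope(n), f.name) for f in usable]
    overlap_bases = 0
    for (e1, n1), (e2, n2) in zip(envs, envs[1:] + envs[:1]):
        gap_start = e1.end % n
        gap_end = e2.start % n
        gap_span = (gap_end - gap_start) % n
        if gap_span == 0 and gap_start == gap_end and e1 is not e2:
            continue
        # negative gap (overlapping genes): overlap belongs to both coding loci
        ov = (gap_start - gap_end) % n
        if 0 < ov <= e1.span(n):
            overlap_bases += ov
            logger.info("%s: features %s/%s overlap by %d bp; excluded from "
                        "spacers", genome.id, n1, n2, ov)
            continue
        pieces = _clip_to_scope(gap_start, gap_span, n, a, b,
                                ir_copies == "one")
        for pi, piece in enumerate(pieces):
            sname = f"{n1}-{n2}" + (f" part {pi + 1}" if len(pieces) > 1 else "")
            keep_or_discard(LocusDef(sname, "noncoding",
                                     _region_label(structure, piece)),
                            genome.fragment(piece), (piece,))

    report.n_overlap_bases = overlap_bases
    covered = scope[scope_sel]
    report.assigned_bases = int((covered > 0).sum() - (covered == 3).sum())
    report.residual_bases = int((covered == 3).sum() + (covered == 0).sum())
    return loci, report


def _clip_to_scope(start: int, span: int, n: int, irb_start: int, irb_end: int,
                   skip_irb: bool) -> list[Interval]:
    """Clip a (possibly wrapping) gap to the LSC+SSC+IRa scope.

    An origin-crossing gap untouched by the IRb stays one wrapping interval.
    """
    if span <= 0:
        return []
    pieces: list[tuple[int, int]] = []
    if start + span <= n:
        segs = [(start, start + span)]
    else:
        segs = [(start, n), (0, start + span - n)]
    for s, e in segs:
        if not skip_irb or e <= irb_start or s >= irb_end:
            pieces.append((s, e))
        else:
            if s < irb_start:
                pieces.append((s, irb_start))
            if e > irb_end:
                pieces.append((irb_end, e))
    pieces = [(s, e) for s, e in pieces if e > s]
    # re-join the two halves of an origin-crossing gap
    tail = next((p for p in pieces if p[1] == n), None)
    head = next((p for p in pieces if p[0] == 0), None)
    if start + span > n and tail and head and tail != head:
        pieces = [p for p in pieces if p not in (tail, head)]
        return [Interval(tail[0], head[1], wraps=True)] + \
            [Interval(s, e) for s, e in pieces]
    return [Interval(s, e) for s, e in pieces]


def collect_homologs(per_taxon: Mapping[str, Sequence[ExtractedLocus]],
                     min_taxa: int | None = None) -> list[LocusSet]:
    """Group per-genome loci by name into cross-taxon locus sets.

    Loci present in fewer than ``min_taxa`` genomes (default: all of them)
    are excluded from downstream statistics and logged.
    """
    if not per_taxon:
        return []
    k = len(per_taxon)
    if min_taxa is None:
        min_taxa = k
    by_name: dict[str, dict[str, ExtractedLocus]] = {}
    for taxon, loci in per_taxon.items():
        for lx in loci:
            by_name.setdefault(lx.locus.name, {})[taxon] = lx
    sets: list[LocusSet] = []
    for name in sorted(by_name):
        members = by_name[name]
        if len(members) < min_taxa:
            logger.info("locus %s present in %d/%d taxa; excluded", name,
                        len(members), k)
            continue
        lengths = [len(lx.seq) for lx in members.values()]
        if max(lengths) > 10 * min(lengths):
            logger.warning("locus %s length range %d-%d exceeds 10x ratio",
                           name, min(lengths), max(lengths))
        any_locus = next(iter(members.values())).locus
        sets.append(LocusSet(any_locus,
                             {t: lx.seq for t, lx in sorted(members.items())},
                             (min(lengths), max(lengths))))
    return sets
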