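"""Plastome sequence / annotation I/O and circular-coordinate arithmetic.

Internally every coordinate is 0-based, half-open.  Files follow the usual
conventions of their formats (GFF3 and the feature-table dialect are 1-based,
inclusive); conversion happens at the read/write boundary.  Circular features
that cross the origin of the linearised sequence carry ``wraps=True`` instead
of being split into parts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: feature kinds understood by the downstream analyses
VALID_KINDS = ("CDS", "tRNA", "rRNA", "intron", "spacer")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def complement(seq: str) -> str:
    """Base-wise complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement; an involution on the normalized alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str, *, label: str = "?") -> str:
    """Uppercase, map U->T, and map any residual ambiguity code to N.

    The number of non-ACGTN characters replaced is logged: downstream
    statistics treat only unambiguous bases.
    """
    s = seq.upper().replace("U", "T")
    n_amb = len(_NON_ACGTN.findall(s))
    if n_amb:
        logger.info("%s: %d non-ACGTN characters normalized to N", label, n_amb)
        s = _NON_ACGTN.sub("N", s)
    return s


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval; ``wraps`` marks origin-crossing intervals.

    For a wrapping interval the covered positions are
    ``[start, genome_length) + [0, end)``.
    """

    start: int
    end: int
    wraps: bool = False

    def span(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("wrapping interval requires genome_length for span()")
        return genome_length - self.start + self.end

    def contains(self, pos: int) -> bool:
        if not self.wraps:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def positions(self, genome_length: int | None = None) -> range | list[int]:
        if not self.wraps:
            return range(self.start, self.end)
        if genome_length is None:
            raise ValueError("wrapping interval requires genome_length")
        return list(range(self.start, genome_length)) + list(range(0, self.end))


def make_interval(start: int, span: int, genome_length: int) -> Interval:
    """Interval of ``span`` bases beginning at ``start`` on a circle."""
    if span <= 0 or span > genome_length:
        raise ValueError(f"invalid span {span} for genome of {genome_length} bp")
    start %= genome_length
    end = start + span
    if end <= genome_length:
        return Interval(start, end, wraps=False)
    return Interval(start, end - genome_length, wraps=True)


@dataclass(frozen=True)
class CircularGenome:
    """A plastome: normalized nucleotide sequence plus circular topology."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        if _NON_ACGTN.search(self.seq) or self.seq != self.seq.upper():
            raise ValueError(
                f"genome {self.id!r}: sequence not normalized (use normalize_seq)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        return self.seq[pos % self.length]

    def fragment(self, interval: Interval) -> str:
        """Sequence covered by ``interval`` (handles origin wrap)."""
        if not interval.wraps:
            return self.seq[interval.start : interval.end]
        if not self.circular:
            raise ValueError("wrapping interval on a non-circular genome")
        return self.seq[interval.start :] + self.seq[: interval.end]

    def rotate(self, offset: int) -> "CircularGenome":
        """New genome whose origin is the current position ``offset``."""
        if not self.circular:
            raise ValueError("cannot rotate a non-circular genome")
        offset %= self.length
        return replace(self, seq=self.seq[offset:] + self.seq[:offset])

    def gc_fraction(self) -> float:
        """(G+C)/(A+C+G+T); ambiguous bases excluded from the denominator."""
        gc = self.seq.count("G") + self.seq.count("C")
        acgt = gc + self.seq.count("A") + self.seq.count("T")
        return gc / acgt if acgt else float("nan")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature: one or more exon parts on one strand."""

    name: str
    kind: str
    strand: str
    parts: tuple[Interval, ...]
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no parts")
        if self.kind in ("intron", "spacer") and len(self.parts) != 1:
            raise ValueError(f"{self.kind} feature {self.name!r} must have one part")

    def envelope(self, genome_length: int) -> Interval:
        """Smallest interval covering all parts (gene start to gene end)."""
        first, last = self.parts[0], self.parts[-1]
        if len(self.parts) == 1:
            return first
        start, end = first.start, last.end
        wraps = last.wraps or first.wraps or end <= start
        return Interval(start, end, wraps=wraps)

    def span(self, genome_length: int) -> int:
        return sum(p.span(genome_length) for p in self.parts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular: bool = True) -> list[CircularGenome]:
    """Read a (multi-record) FASTA into normalized circular genomes.

    Empty files and duplicate record ids are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    genomes: list[CircularGenome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genomes.append(
            CircularGenome(rec.id, normalize_seq(str(rec.seq), label=rec.id), circular)
        )
    return genomes


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotations: GFF3 and the feature-table TSV dialect
# ---------------------------------------------------------------------------

_GFF_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _part_from_1based(start1: int, end1: int, genome_length: int | None,
                      circular: bool, label: str) -> Interval:
    """Convert 1-based inclusive file coordinates to an internal Interval."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"{label}: invalid coordinates {start1}..{end1}")
    if genome_length is not None and end1 > genome_length:
        if not circular:
            raise ValueError(
                f"{label}: feature end {end1} beyond genome length {genome_length} "
                "on a non-circular genome"
            )
        return Interval(start1 - 1, end1 - genome_length, wraps=True)
    return Interval(start1 - 1, end1, wraps=False)


def read_annotations(path: str | Path, fmt: str = "gff3", *,
                     genome_length: int | None = None,
                     circular: bool = True) -> list[GeneFeature]:
    """Read gene features from GFF3 or the feature-table TSV dialect.

    File coordinates are 1-based inclusive; multi-exon entries sharing an ID
    (GFF3) are merged into a single feature with ordered parts.
    """
    if fmt == "gff3":
        return _read_gff3(path, genome_length, circular)
    if fmt == "feature_table":
        return _read_feature_table(path, genome_length, circular)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gff3(path: str | Path, genome_length: int | None,
               circular: bool) -> list[GeneFeature]:
    from gffutils.iterators import DataIterator

    grouped: dict[str, dict] = {}
    order: list[str] = []
    for f in DataIterator(str(path)):
        kind = _GFF_KINDS.get(f.featuretype)
        if kind is None:
            continue
        attrs = f.attributes
        name = (attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or [None])[0]
        key = (attrs.get("ID") or [name])[0]
        if key is None:
            raise ValueError(f"{path}: feature without ID or Name at {f.start}")
        pseudo = "pseudo" in attrs or "pseudogene" in attrs or (
            attrs.get("gene_biotype", [""])[0] == "pseudogene")
        part = _part_from_1based(f.start, f.end, genome_length, circular,
                                 f"{path}:{key}")
        entry = grouped.setdefault(
            key, {"name": name or key, "kind": kind, "strand": f.strand or "+",
                  "parts": [], "pseudo": False})
        entry["parts"].append(part)
        entry["pseudo"] = entry["pseudo"] or pseudo
        if key not in order:
            order.append(key)
    features = []
    for key in order:
        e = grouped[key]
        parts = tuple(sorted(e["parts"], key=lambda p: (p.start, p.end)))
        features.append(GeneFeature(e["name"], e["kind"], e["strand"], parts,
                                    e["pseudo"]))
    return features


def _read_feature_table(path: str | Path, genome_length: int | None,
                        circular: bool) -> list[GeneFeature]:
    """Dialect: name<TAB>kind<TAB>strand<TAB>ranges[<TAB>pseudo].

    ``ranges`` is a comma-separated list of 1-based inclusive ``start..end``.
    Lines starting with '#' are comments.
    """
    features: list[GeneFeature] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(f"{path}:{ln}: expected >=4 tab-separated columns")
        name, kind, strand, ranges = cols[:4]
        pseudo = len(cols) > 4 and cols[4].strip() in ("1", "true", "True", "pseudo")
        parts = []
        for rng in ranges.split(","):
            m = re.fullmatch(r"\s*(\d+)\.\.(\d+)\s*", rng)
            if not m:
                raise ValueError(f"{path}:{ln}: bad range {rng!r}")
            s1, e1 = int(m.group(1)), int(m.group(2))
            if e1 < s1:
                # origin-crossing part written as start..end with end < start
                if not circular:
                    raise ValueError(f"{path}:{ln}: wrapping range on linear genome")
                parts.append(Interval(s1 - 1, e1, wraps=True))
            else:
                parts.append(_part_from_1based(s1, e1, genome_length, circular,
                                               f"{path}:{ln}"))
        features.append(GeneFeature(name, kind, strand, tuple(parts), pseudo))
    return features


def _part_to_1based(part: Interval, genome_length: int | None) -> str:
    if not part.wraps:
        return f"{part.start + 1}..{part.end}"
    return f"{part.start + 1}..{part.end}"


def write_annotations(features: Sequence[GeneFeature], path: str | Path,
                      fmt: str = "feature_table", *, seqid: str = "genome",
                      genome_length: int | None = None) -> None:
    """Write features back out with 1-based inclusive coordinates."""
    lines: list[str] = []
    if fmt == "feature_table":
        lines.append("# name\tkind\tstrand\tparts\tpseudo")
        for f in features:
            ranges = ",".join(_part_to_1based(p, genome_length) for p in f.parts)
            lines.append(f"{f.name}\t{f.kind}\t{f.strand}\t{ranges}\t"
                         f"{1 if f.pseudo else 0}")
    elif fmt == "gff3":
        lines.append("##gff-version 3")
        for i, f in enumerate(features):
            attrs = f"ID={f.name}.{i};Name={f.name}"
            if f.pseudo:
                attrs += ";pseudo=true"
            for p in f.parts:
                if p.wraps:
                    if genome_length is None:
                        raise ValueError("wrapping part needs genome_length for GFF3")
                    start1, end1 = p.start + 1, genome_length + p.end
                else:
                    start1, end1 = p.start + 1, p.end
                lines.append("\t".join([seqid, "plastocompare", f.kind, str(start1),
                                        str(end1), ".", f.strand, ".", attrs]))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinate transforms used by canonicalization and the simulator
# ---------------------------------------------------------------------------

def shift_interval(iv: Interval, offset: int, genome_length: int) -> Interval:
    """Interval after rotating the genome origin to position ``offset``."""
    return make_interval((iv.start - offset) % genome_length,
                         iv.span(genome_length), genome_length)


def shift_feature(f: GeneFeature, offset: int, genome_length: int) -> GeneFeature:
    parts = tuple(sorted((shift_interval(p, offset, genome_length) for p in f.parts),
                         key=lambda p: (p.start, p.end)))
    return replace(f, parts=parts)


def flip_interval(iv: Interval, genome_length: int) -> Interval:
    """Interval after reverse-complementing the whole genome."""
    span = iv.span(genome_length)
    new_start = (genome_length - iv.end) % genome_length if not iv.wraps else (
        genome_length - iv.end) % genome_length
    return make_interval(new_start, span, genome_length)


def flip_feature(f: GeneFeature, genome_length: int) -> GeneFeature:
    parts = tuple(sorted((flip_interval(p, genome_length) for p in f.parts),
                         key=lambda p: (p.start, p.end)))
    strand = "-" if f.strand == "+" else "+"
    return replace(f, parts=parts, strand=strand)
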