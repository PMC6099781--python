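"""Quadripartite structure detection and IR-junction comparison.

A typical plastome is a circle partitioned as LSC -> IRb -> SSC -> IRa where
IRb is the exact reverse complement of IRa.  ``detect_ir`` finds the maximal
exact inverted-repeat pair by seed-and-extend (circularity handled by doubling
the sequence); the longer single-copy arc is labelled LSC.  Junction ``J``
between region X and region Y is the 0-based coordinate of the first base of
Y, so JLB/JSB/JSA/JLA are the first bases of IRb/SSC/IRa/LSC respectively.

A gene *spans* a junction only when it covers bases on both sides of the
boundary (strictly interior overlap); a gene whose end abuts the junction is
"upstream" at distance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .plastome_io import (CircularGenome, GeneFeature, Interval, complement,
                          flip_feature, make_interval, revcomp, shift_feature)

logger = logging.getLogger(__name__)

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


class NoInvertedRepeatError(ValueError):
    """Raised when no inverted-repeat pair of the required length exists."""


class AmbiguousInvertedRepeatError(ValueError):
    """Raised when several non-identical IR pairs tie for maximal length."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            "multiple maximal inverted-repeat candidates: "
            + ", ".join(f"(start1={a}, start2={b}, len={L})" for a, b, L in candidates)
        )


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals plus the four junction coordinates."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int

    @property
    def jlb(self) -> int:
        return self.irb.start

    @property
    def jsb(self) -> int:
        return self.ssc.start

    @property
    def jsa(self) -> int:
        return self.ira.start

    @property
    def jla(self) -> int:
        return self.lsc.start

    def junctions(self) -> dict[str, int]:
        return {"JLB": self.jlb, "JSB": self.jsb, "JSA": self.jsa, "JLA": self.jla}

    @property
    def ir_length(self) -> int:
        return self.ira.span(self.genome_length)

    @property
    def lsc_length(self) -> int:
        return self.lsc.span(self.genome_length)

    @property
    def ssc_length(self) -> int:
        return self.ssc.span(self.genome_length)

    def region_of(self, pos: int) -> str:
        for name, iv in (("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc),
                         ("IRa", self.ira)):
            if iv.contains(pos % self.genome_length):
                return name
        raise AssertionError("quadripartite intervals do not tile the circle")


@dataclass(frozen=True)
class JunctionGeneRecord:
    junction: str
    gene: str
    relation: str  # spans | upstream | downstream
    distance: int  # 0 when spans; else bases between nearest gene end and junction


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _inverted_runs(seq: str, min_len: int, seed_len: int) -> list[tuple[int, int, int]]:
    """Maximal inverted-match runs (i, j, L) with i < j on the given string.

    A run satisfies seq[j:j+L] == revcomp(seq[i:i+L]) and cannot be extended.
    Matched character pairs lie on the anti-diagonal c = i + j + L - 1 where
    seq[y] == complement(seq[c-y]).
    """
    m = len(seq)
    k = min(seed_len, min_len)
    index: dict[str, list[int]] = {}
    for i in range(m - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)

    comp = complement
    covered: dict[int, list[tuple[int, int]]] = {}
    runs: list[tuple[int, int, int]] = []  # (c, y0, y1)
    for kmer, positions in index.items():
        partner = revcomp(kmer)
        if partner < kmer:
            continue  # each unordered bucket pair handled once
        partner_pos = index.get(partner)
        if not partner_pos:
            continue
        for i in positions:
            for j in partner_pos:
                if partner == kmer and j <= i:
                    continue
                c = i + j + k - 1
                y = max(i, j)
                spans_c = covered.get(c)
                if spans_c and any(y0 <= y and y + k - 1 <= y1 for y0, y1 in spans_c):
                    continue
                # extend the run containing y .. y+k-1 on anti-diagonal c
                y0, y1 = y, y + k - 1
                while y1 + 1 < m and c - y1 - 1 >= 0 and y1 - y0 + 1 < m:
                    a, b = seq[y1 + 1], seq[c - y1 - 1]
                    if a == "N" or b == "N" or a != comp(b):
                        break
                    y1 += 1
                while y0 - 1 >= 0 and c - y0 + 1 < m and y1 - y0 + 1 < m:
                    a, b = seq[y0 - 1], seq[c - y0 + 1]
                    if a == "N" or b == "N" or a != comp(b):
                        break
                    y0 -= 1
                covered.setdefault(c, []).append((y0, y1))
                if y1 - y0 + 1 >= min_len and y0 + y1 > c:
                    runs.append((c, y0, y1))
    out = []
    for c, y0, y1 in runs:
        out.append((c - y1, y0, y1 - y0 + 1))  # (i, j, L) with i < j
    return out


def detect_ir(genome: CircularGenome, min_ir_len: int = 1000,
              seed_len: int = 25) -> QuadripartiteStructure:
    """Locate the maximal exact inverted-repeat pair and partition the circle.

    Raises :class:`NoInvertedRepeatError` when nothing of length
    ``min_ir_len`` exists (cf. plastomes that lost one IR copy), and
    :class:`AmbiguousInvertedRepeatError` when distinct candidate pairs tie.
    """
    if min_ir_len < 2:
        raise ValueError("min_ir_len must be >= 2")
    n = genome.length
    doubled = genome.seq + genome.seq if genome.circular else genome.seq

    candidates: dict[tuple[int, int, int], None] = {}
    for i, j, L in _inverted_runs(doubled, min_ir_len, seed_len):
        if L > n:
            L = n
        p, q = sorted((i % n, j % n))
        arc1 = (q - p - L) % n
        arc2 = n - 2 * L - arc1
        if arc2 < 0 or 2 * L > n:
            continue  # copies overlap on the circle
        candidates[(p, q, L)] = None

    if not candidates:
        raise NoInvertedRepeatError(
            f"{genome.id}: no inverted repeat >= {min_ir_len} bp")

    best_len = max(L for _, _, L in candidates)
    best = sorted({(p, q) for p, q, L in candidates if L == best_len})
    if len(best) > 1:
        raise AmbiguousInvertedRepeatError([(p, q, best_len) for p, q in best])

    p, q = best[0]
    L = best_len
    arc1 = (q - p - L) % n  # arc from end of copy@p to start of copy@q
    arc2 = n - 2 * L - arc1  # arc from end of copy@q to start of copy@p
    if arc1 == 0 or arc2 == 0:
        raise NoInvertedRepeatError(
            f"{genome.id}: IR copies are adjacent; no single-copy regions")
    if arc1 == arc2:
        raise AmbiguousInvertedRepeatError([(p, q, L)])

    copy_p = make_interval(p, L, n)
    copy_q = make_interval(q, L, n)
    if arc1 > arc2:
        # LSC runs from end of copy@p to q: copy@q is IRb, copy@p is IRa
        lsc = make_interval((p + L) % n, arc1, n)
        irb, ira = copy_q, copy_p
        ssc = make_interval((q + L) % n, arc2, n)
    else:
        lsc = make_interval((q + L) % n, arc2, n)
        irb, ira = copy_p, copy_q
        ssc = make_interval((p + L) % n, arc1, n)

    structure = QuadripartiteStructure(lsc, irb, ssc, ira, n)
    assert (structure.lsc_length + structure.ssc_length + 2 * structure.ir_length
            == n)
    if genome.fragment(irb) != revcomp(genome.fragment(ira)):
        raise AssertionError("detected IR copies are not exact reverse complements")
    return structure


# ---------------------------------------------------------------------------
# canonical orientation / rotation
# ---------------------------------------------------------------------------

def canonicalize(genome: CircularGenome,
                 features: Sequence[GeneFeature] = (),
                 structure: QuadripartiteStructure | None = None,
                 ) -> tuple[CircularGenome, list[GeneFeature], QuadripartiteStructure]:
    """Rotate (and possibly flip) so the LSC starts at position 0.

    Orientation is chosen so that psbA/trnH lie in the first half of the LSC
    when annotated, otherwise by the lexicographically smaller LSC string —
    a deterministic convention for reproducible reports.
    """
    if structure is None:
        structure = detect_ir(genome)
    n = genome.length

    def _rotated(g, feats, st):
        off = st.lsc.start
        g2 = g.rotate(off)
        f2 = [shift_feature(f, off, n) for f in feats]
        lsc = make_interval(0, st.lsc_length, n)
        irb = make_interval(st.lsc_length, st.ir_length, n)
        ssc = make_interval(st.lsc_length + st.ir_length, st.ssc_length, n)
        ira = make_interval(st.lsc_length + st.ir_length + st.ssc_length,
                            st.ir_length, n)
        return g2, f2, QuadripartiteStructure(lsc, irb, ssc, ira, n)

    g_fwd, f_fwd, st_fwd = _rotated(genome, features, structure)

    flipped = CircularGenome(genome.id, revcomp(genome.seq), genome.circular)
    feats_flipped = [flip_feature(f, n) for f in features]
    st_flipped = QuadripartiteStructure(
        lsc=_flip_iv(structure.lsc, n), irb=_flip_iv(structure.ira, n),
        ssc=_flip_iv(structure.ssc, n), ira=_flip_iv(structure.irb, n),
        genome_length=n)
    g_rev, f_rev, st_rev = _rotated(flipped, feats_flipped, st_flipped)

    marker_names = {"psbA", "trnH", "trnH-GUG"}
    markers_fwd = [f for f in f_fwd if f.name in marker_names]
    if markers_fwd:
        pos = min(f.parts[0].start for f in markers_fwd)
        if pos < st_fwd.lsc_length // 2:
            return g_fwd, f_fwd, st_fwd
        return g_rev, f_rev, st_rev
    lsc_fwd = g_fwd.fragment(st_fwd.lsc)
    lsc_rev = g_rev.fragment(st_rev.lsc)
    return (g_fwd, f_fwd, st_fwd) if lsc_fwd <= lsc_rev else (g_rev, f_rev, st_rev)


def _flip_iv(iv: Interval, n: int) -> Interval:
    return make_interval((n - (iv.end if not iv.wraps else iv.end)) % n,
                         iv.span(n), n)


# ---------------------------------------------------------------------------
# junction reports
# ---------------------------------------------------------------------------

def junction_report(structure: QuadripartiteStructure,
                    features: Sequence[GeneFeature]) -> list[JunctionGeneRecord]:
    """Spanning gene, else nearest gene on each side, for all four junctions."""
    n = structure.genome_length
    records: list[JunctionGeneRecord] = []
    for jname, jpos in structure.junctions().items():
        spanning = []
        for f in features:
            env = f.envelope(n)
            if env.contains(jpos) and env.contains((jpos - 1) % n):
                spanning.append(f.name)
        if spanning:
            for g in sorted(spanning):
                records.append(JunctionGeneRecord(jname, g, "spans", 0))
            continue
        up: tuple[int, str] | None = None
        down: tuple[int, str] | None = None
        for f in features:
            env = f.envelope(n)
            d_up = (jpos - env.end) % n
            d_down = (env.start - jpos) % n
            if up is None or (d_up, f.name) < up:
                up = (d_up, f.name)
            if down is None or (d_down, f.name) < down:
                down = (d_down, f.name)
        if up is not None:
            records.append(JunctionGeneRecord(jname, up[1], "upstream", up[0]))
        if down is not None:
            records.append(JunctionGeneRecord(jname, down[1], "downstream", down[0]))
    return records


def gene_regions(structure: QuadripartiteStructure,
                 features: Sequence[GeneFeature]) -> pd.DataFrame:
    """Region assignment per gene: the region wholly containing it, else the
    junction it spans (used to report shifts such as "rps19 into the LSC")."""
    n = structure.genome_length
    rows = []
    for f in features:
        env = f.envelope(n)
        r_start = structure.region_of(env.start)
        r_last = structure.region_of((env.end - 1) % n)
        rows.append({"gene": f.name, "kind": f.kind,
                     "region": r_start if r_start == r_last
                     else f"{r_start}/{r_last}"})
    return pd.DataFrame(rows, columns=["gene", "kind", "region"])


def compare_junctions(items: Sequence[tuple[str, QuadripartiteStructure,
                                            Sequence[GeneFeature]]]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-genome junction comparison.

    Returns a long-format table (genome, junction, gene, relation, distance)
    and a per-genome summary with region lengths and an "IR type" label
    derived from the identity and relation of the JSB/JSA genes.
    """
    if len(items) < 2:
        raise ValueError("compare_junctions requires >= 2 genomes")
    long_rows = []
    summaries = []
    type_keys: dict[tuple, str] = {}
    for gid, structure, features in items:
        recs = junction_report(structure, features)
        for r in recs:
            long_rows.append({"genome": gid, "junction": r.junction, "gene": r.gene,
                              "relation": r.relation, "distance": r.distance})
        key_parts = []
        for jname in ("JSB", "JSA"):
            jrecs = [r for r in recs if r.junction == jname]
            spans = [r for r in jrecs if r.relation == "spans"]
            if spans:
                chosen = min(spans, key=lambda r: r.gene)
            elif jrecs:
                chosen = min(jrecs, key=lambda r: (r.distance, r.gene, r.relation))
            else:
                chosen = JunctionGeneRecord(jname, "-", "none", 0)
            key_parts.append((jname, chosen.gene, chosen.relation))
        key = tuple(key_parts)
        if key not in type_keys:
            type_keys[key] = f"IR-type-{len(type_keys) + 1}"
        summaries.append({
            "genome": gid, "length": structure.genome_length,
            "lsc_length": structure.lsc_length, "ssc_length": structure.ssc_length,
            "ir_length": structure.ir_length, "ir_type": type_keys[key],
        })
    table = pd.DataFrame(long_rows,
                         columns=["genome", "junction", "gene", "relation",
                                  "distance"])
    genomes = pd.DataFrame(summaries)
    return table, genomes
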