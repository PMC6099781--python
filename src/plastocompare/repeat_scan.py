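"""Dispersed-repeat and microsatellite (SSR) census.

Dispersed repeats come in four flavours, defined by the relation between the
two copies: forward (identical), palindromic (reverse complement), reverse
(reversed) and complement (complemented).  A hit is *maximal*: neither copy
can be extended on either side while preserving the relation.  Detection is
seed-and-extend over exact k-mer matches; positions containing N never
participate.

SSRs are maximal tandem arrays of a 1-6 bp primitive motif.  The per-unit
minimum copy numbers default to 10/6/5/5/5/5 for mono- through
hexanucleotides.  Partial trailing units do not count toward copies, a run
whose motif is itself periodic is reported only at its primitive period, and
runs are split at N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .plastome_io import CircularGenome, Interval, complement, revcomp
from .quadripartite import QuadripartiteStructure

logger = logging.getLogger(__name__)

REPEAT_TYPES = ("forward", "palindromic", "reverse", "complement")

#: MISA-style minimum copy numbers per motif length
MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class RepeatHit:
    rtype: str
    pos1: Interval
    pos2: Interval
    length: int
    is_ir_pair: bool = False


@dataclass(frozen=True)
class SSRHit:
    motif: str  # canonical: lexicographically minimal rotation
    unit: int
    copies: int
    locus: Interval


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _match_fwd(a: str, b: str) -> bool:
    return a == b and a != "N"


def _match_comp(a: str, b: str) -> bool:
    return a != "N" and b == complement(a)


def _diagonal_hits(seq: str, k: int, min_len: int, match, partner_key,
                   rtype: str, index) -> list[RepeatHit]:
    """Forward/complement hits: both copies advance together (diagonal runs)."""
    n = len(seq)
    covered: dict[int, list[tuple[int, int]]] = {}
    hits: list[RepeatHit] = []
    for kmer, positions in index.items():
        partner = partner_key(kmer)
        if partner < kmer:
            continue
        partner_pos = index.get(partner)
        if not partner_pos:
            continue
        same = partner == kmer
        for i in positions:
            for j in partner_pos:
                if same and j <= i:
                    continue
                a, b = (i, j) if i < j else (j, i)
                # seed asserts relation between seq[a..] and seq[b..]; for
                # complement the relation is symmetric so ordering is free
                d = b - a
                if d == 0:
                    continue
                spans_d = covered.get(d)
                if spans_d and any(x0 <= a and a + k - 1 <= x1 for x0, x1 in spans_d):
                    continue
                x0, x1 = a, a + k - 1
                while x1 + 1 + d < n and match(seq[x1 + 1], seq[x1 + 1 + d]):
                    x1 += 1
                while x0 - 1 >= 0 and match(seq[x0 - 1], seq[x0 - 1 + d]):
                    x0 -= 1
                covered.setdefault(d, []).append((x0, x1))
                L = x1 - x0 + 1
                if L >= min_len:
                    hits.append(RepeatHit(rtype, Interval(x0, x1 + 1),
                                          Interval(x0 + d, x1 + 1 + d), L))
    return hits


def _antidiagonal_hits(seq: str, k: int, min_len: int, match, partner_key,
                       rtype: str, index) -> list[RepeatHit]:
    """Palindromic/reverse hits: copy2 mirrors copy1 (anti-diagonal runs).

    Matched character pairs satisfy match(seq[c-y], seq[y]) with constant
    c = pos1.start + pos2.end - 1.  A maximal run [y0, y1] yields the hit
    pos1=[c-y1, c-y0+1), pos2=[y0, y1+1); runs with y0+y1 <= c are the mirror
    images (or self-mirrors) of runs already reported.
    """
    n = len(seq)
    covered: dict[int, list[tuple[int, int]]] = {}
    hits: list[RepeatHit] = []
    for kmer, positions in index.items():
        partner = partner_key(kmer)
        if partner < kmer:
            continue
        partner_pos = index.get(partner)
        if not partner_pos:
            continue
        same = partner == kmer
        for i in positions:
            for j in partner_pos:
                if same and j < i:
                    continue
                if i == j:
                    continue  # self-mirror seed can only yield i == j hits
                c = i + j + k - 1
                y = max(i, j)
                spans_c = covered.get(c)
                if spans_c and any(y0 <= y and y + k - 1 <= y1 for y0, y1 in spans_c):
                    continue
                y0, y1 = y, y + k - 1
                while y1 + 1 < n and c - y1 - 1 >= 0 and match(seq[c - y1 - 1],
                                                               seq[y1 + 1]):
                    y1 += 1
                while y0 - 1 >= 0 and c - y0 + 1 < n and match(seq[c - y0 + 1],
                                                               seq[y0 - 1]):
                    y0 -= 1
                covered.setdefault(c, []).append((y0, y1))
                L = y1 - y0 + 1
                if L >= min_len and y0 + y1 > c:
                    hits.append(RepeatHit(rtype, Interval(c - y1, c - y0 + 1),
                                          Interval(y0, y1 + 1), L))
    return hits


def find_repeats(genome: CircularGenome, min_repeat_len: int = 8,
                 types: Sequence[str] = REPEAT_TYPES,
                 structure: QuadripartiteStructure | None = None,
                 seed_len: int | None = None) -> list[RepeatHit]:
    """All maximal exact dispersed repeats of the requested types.

    The scan is linear (no origin-crossing hits).  When ``structure`` is
    given, the genome-scale IRa-vs-IRb palindromic hit is flagged
    ``is_ir_pair`` rather than dropped.
    """
    if min_repeat_len < 2:
        raise ValueError("min_repeat_len must be >= 2")
    unknown = set(types) - set(REPEAT_TYPES)
    if unknown:
        raise ValueError(f"unknown repeat types: {sorted(unknown)}")
    k = min(seed_len or 12, min_repeat_len)
    seq = genome.seq
    index = _kmer_index(seq, k)

    hits: list[RepeatHit] = []
    if "forward" in types:
        hits += _diagonal_hits(seq, k, min_repeat_len, _match_fwd,
                               lambda s: s, "forward", index)
    if "complement" in types:
        hits += _diagonal_hits(seq, k, min_repeat_len, _match_comp,
                               complement, "complement", index)
    if "palindromic" in types:
        hits += _antidiagonal_hits(seq, k, min_repeat_len, _match_comp,
                                   revcomp, "palindromic", index)
    if "reverse" in types:
        hits += _antidiagonal_hits(seq, k, min_repeat_len, _match_fwd,
                                   lambda s: s[::-1], "reverse", index)

    if structure is not None:
        flagged = []
        for h in hits:
            is_ir = (h.rtype == "palindromic" and h.length >= structure.ir_length
                     and _overlaps(h.pos1, structure.irb, structure.genome_length)
                     and _overlaps(h.pos2, structure.ira, structure.genome_length))
            flagged.append(RepeatHit(h.rtype, h.pos1, h.pos2, h.length, is_ir)
                           if is_ir else h)
        hits = flagged
    hits.sort(key=lambda h: (h.pos1.start, h.pos2.start, h.rtype))
    return hits


def _overlaps(a: Interval, b: Interval, n: int) -> bool:
    pa = set(range(a.start, a.end)) if not a.wraps else set(a.positions(n))
    pb = set(b.positions(n)) if b.wraps else set(range(b.start, b.end))
    return bool(pa & pb)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def _is_periodic(motif: str) -> bool:
    """True when the motif is a whole-number repetition of a shorter unit."""
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[: p] * (u // p):
            return True
    return False


def canonical_rotation(motif: str) -> str:
    """Lexicographically minimal rotation, used as the canonical motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(genome: CircularGenome,
              min_copies: Mapping[int, int] | None = None,
              max_unit: int = 6) -> list[SSRHit]:
    """All maximal tandem arrays meeting the per-unit minimum copy numbers.

    For unit size u, positions x with seq[x] == seq[x+u] (both unambiguous)
    form match runs; a maximal run of r such positions is a tandem array of
    r + u characters, i.e. floor((r+u)/u) full copies.  The reported locus
    covers the full copies only, and the motif must be primitive (aperiodic).
    """
    mins = dict(MIN_COPIES)
    if min_copies:
        mins.update(min_copies)
    seq = genome.seq
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    hits: list[SSRHit] = []
    for u in range(1, max_unit + 1):
        if n <= u:
            break
        m = (arr[:-u] == arr[u:]) & ~is_n[:-u] & ~is_n[u:]
        # maximal runs of True in m
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive, in match-array coords
        for a, e in zip(starts, ends):
            r = e - a
            copies = (r + u) // u
            if copies < mins.get(u, 5):
                continue
            motif = seq[a : a + u]
            if _is_periodic(motif):
                continue
            hits.append(SSRHit(canonical_rotation(motif), u, int(copies),
                               Interval(int(a), int(a) + u * int(copies))))
    hits.sort(key=lambda h: (h.locus.start, h.unit))
    return hits


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatSummary:
    repeat_counts: dict[str, int]
    ssr_unit_counts: dict[int, int]
    total_repeats: int
    total_ssrs: int


def repeat_summary(repeat_hits: Sequence[RepeatHit],
                   ssr_hits: Sequence[SSRHit]) -> RepeatSummary:
    """Counts by repeat type and SSR unit size, with grand totals."""
    rc = {t: 0 for t in REPEAT_TYPES}
    for h in repeat_hits:
        rc[h.rtype] += 1
    sc: dict[int, int] = {}
    for s in ssr_hits:
        sc[s.unit] = sc.get(s.unit, 0) + 1
    return RepeatSummary(rc, dict(sorted(sc.items())), len(repeat_hits),
                         len(ssr_hits))
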