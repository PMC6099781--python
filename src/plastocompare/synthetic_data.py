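"""Synthetic plastome generator with full ground truth.

Builds circular quadripartite genomes (LSC -> IRb -> SSC -> IRa, with IRb the
exact reverse complement of IRa), plants gene models at controlled offsets
from the four junctions, plants SSRs and dispersed repeats with guard bases
that make them maximal, screens out accidental repeats above a length
threshold, and evolves the ancestor along a star (or supplied) tree under
Jukes-Cantor substitutions at locus-specific per-site rates.  Evolution is
indel-free by default so locus homology stays positional and the expected
column variability has a closed form; the IR copies co-evolve (one copy is
simulated and mirrored) so the IR identity is preserved exactly.

Default plan dimensions follow the published Olyreae plastomes
(LSC ~83 kb, SSC ~13 kb, IR ~20 kb, 13 taxa); everything scales down for
fast tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .locus_extract import extract_loci
from .plastome_io import (CircularGenome, GeneFeature, Interval, complement,
                          make_interval, revcomp)
from .quadripartite import (JunctionGeneRecord, QuadripartiteStructure)
from .repeat_scan import (MIN_COPIES, RepeatHit, SSRHit, canonical_rotation,
                          find_repeats, find_ssrs)

logger = logging.getLogger(__name__)

_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene to plant: anchored to a region start or to a junction.

    With ``junction`` set, the gene starts at ``junction_position + offset``
    (a negative offset with ``offset + length > 0`` makes the gene span the
    junction).  Otherwise it starts at ``region`` start + offset.
    """

    name: str
    length: int
    kind: str = "CDS"
    strand: str = "+"
    region: str | None = None  # LSC | SSC | IR (meaning IRa)
    junction: str | None = None  # JLB | JSB | JSA | JLA
    offset: int = 0
    intron_lengths: tuple[int, ...] = ()


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    copies: int
    region: str  # LSC | SSC
    offset: int


@dataclass(frozen=True)
class PlantedRepeat:
    length: int
    rtype: str
    region1: str
    offset1: int
    region2: str
    offset2: int


@dataclass(frozen=True)
class SyntheticPlan:
    seed: int
    lsc_len: int = 82935
    ssc_len: int = 12984
    ir_len: int = 19993
    gc: float = 0.387
    taxa: int = 13
    gene_models: tuple[GeneModel, ...] = ()
    planted_ssrs: tuple[PlantedSSR, ...] = ()
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    coding_rate_range: tuple[float, float] = (0.001, 0.010)
    noncoding_rate_range: tuple[float, float] = (0.002, 0.018)
    background_rate: float = 0.002
    locus_rates: Mapping[str, float] | None = None
    locus_min_len: int = 100
    tree_newick: str | None = None
    junction_shifts: Mapping[str, int] = field(default_factory=dict)
    screen_len: int = 12

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region sizes must be positive")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("LSC must be longer than SSC")
        for lo, hi in (self.coding_rate_range, self.noncoding_rate_range):
            if not (0 <= lo <= hi < 0.75):
                raise ValueError("substitution rates must lie in [0, 0.75)")
        if not 0 <= self.background_rate < 0.75:
            raise ValueError("background_rate must lie in [0, 0.75)")
        if self.locus_rates:
            for name, p in self.locus_rates.items():
                if not 0 <= p < 0.75:
                    raise ValueError(f"rate for {name} outside [0, 0.75)")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class GroundTruth:
    junctions: dict[str, int]
    region_lengths: dict[str, int]
    junction_genes: list[JunctionGeneRecord]
    ssrs: list[SSRHit]
    repeats: list[RepeatHit]
    locus_rates: dict[str, float] = field(default_factory=dict)
    tree_newick: str | None = None
    shifts: dict[str, int] = field(default_factory=dict)
    #: genome intervals occupied by planted SSRs/repeats; secondary hits
    #: inside these are consequences of the planted elements
    planted_intervals: list[tuple[int, int]] = field(default_factory=list)


def structure_from_plan(plan: SyntheticPlan) -> QuadripartiteStructure:
    l, r, s = plan.lsc_len, plan.ir_len, plan.ssc_len
    n = plan.genome_length
    return QuadripartiteStructure(
        lsc=make_interval(0, l, n), irb=make_interval(l, r, n),
        ssc=make_interval(l + r, s, n), ira=make_interval(l + r + s, r, n),
        genome_length=n)


# ---------------------------------------------------------------------------
# plan builders
# ---------------------------------------------------------------------------

def build_plan(seed: int, lsc_len: int = 82935, ssc_len: int = 12984,
               ir_len: int = 19993, taxa: int = 13,
               n_lsc_genes: int | None = None, n_ssc_genes: int | None = None,
               n_mono_ssrs: int = 14, n_di_ssrs: int = 1, n_tri_ssrs: int = 1,
               n_forward: int = 10, n_palindromic: int = 6, n_reverse: int = 3,
               n_complement: int = 2, **overrides) -> SyntheticPlan:
    """Assemble a collision-free plan with junction genes, fillers, SSRs and
    dispersed repeats laid out deterministically inside the LSC/SSC."""
    jg = max(90, min(900, ssc_len // 7))  # junction-gene length scale
    psba_len = max(120, min(1000, lsc_len // 12))
    trnh_len = min(75, max(40, ir_len // 20))
    models = [
        GeneModel("psbA", psba_len, kind="CDS", strand="-", junction="JLA",
                  offset=80),
        GeneModel("trnH", trnh_len, kind="tRNA", strand="-", junction="JLA",
                  offset=-(trnh_len + 30)),
        GeneModel("rpl22", jg, junction="JLB", offset=-(jg + 120)),
        GeneModel("rps19", max(60, jg // 3), junction="JLB",
                  offset=-max(20, jg // 8)),
        GeneModel("ndhF", jg, junction="JSB", offset=-max(15, jg // 6),
                  strand="-"),
        GeneModel("rps15", max(60, jg // 3), junction="JSA",
                  offset=-(jg + max(60, jg // 3) + 100), strand="-"),
        GeneModel("ndhH", jg, junction="JSA", offset=-(jg - max(20, jg // 5))),
    ]

    # planted elements live in a reserved yard at the start of the LSC,
    # after psbA and well before the fillers
    yard_cursor = 80 + psba_len + 60
    ssrs: list[PlantedSSR] = []
    rng = np.random.default_rng([seed, 101])
    mono_bases = ["A", "T"]
    for i in range(n_mono_ssrs):
        copies = 10 + int(rng.integers(0, 4))
        ssrs.append(PlantedSSR(mono_bases[i % 2], copies, "LSC", yard_cursor))
        yard_cursor += copies + 6
    for _ in range(n_di_ssrs):
        ssrs.append(PlantedSSR("AT", 6, "LSC", yard_cursor))
        yard_cursor += 12 + 6
    for _ in range(n_tri_ssrs):
        ssrs.append(PlantedSSR("AAG", 5, "LSC", yard_cursor))
        yard_cursor += 15 + 6

    repeats: list[PlantedRepeat] = []
    for rtype, count in (("forward", n_forward), ("palindromic", n_palindromic),
                         ("reverse", n_reverse), ("complement", n_complement)):
        for i in range(count):
            L = 15 + int(rng.integers(0, 26))
            repeats.append(PlantedRepeat(L, rtype, "LSC", yard_cursor,
                                         "LSC", yard_cursor + L + 6))
            yard_cursor += 2 * L + 12

    # fillers occupy the rest of the LSC (up to rpl22) and the SSC middle
    if n_lsc_genes is None:
        n_lsc_genes = max(2, lsc_len // 2500)
    if n_ssc_genes is None:
        n_ssc_genes = max(1, ssc_len // 2800)
    lsc_zone = (yard_cursor + 100, lsc_len - (jg + 120) - 200)
    models += _fillers("lsg", "LSC", lsc_zone, n_lsc_genes)
    ssc_zone = (max(20, jg), ssc_len - (2 * jg + max(60, jg // 3) + 260))
    models += _fillers("ssg", "SSC", ssc_zone, n_ssc_genes)

    return SyntheticPlan(seed=seed, lsc_len=lsc_len, ssc_len=ssc_len,
                         ir_len=ir_len, taxa=taxa, gene_models=tuple(models),
                         planted_ssrs=tuple(ssrs),
                         planted_repeats=tuple(repeats), **overrides)


def _fillers(prefix: str, region: str, zone: tuple[int, int],
             count: int) -> list[GeneModel]:
    lo, hi = zone
    if hi - lo < count * 220:
        raise ValueError(f"region {region} too small for {count} filler genes")
    stride = (hi - lo) // count
    glen = max(120, int(stride * 0.55))
    models = []
    for i in range(count):
        start = lo + i * stride
        introns = (max(60, int(stride * 0.15)),) if i % 5 == 4 else ()
        models.append(GeneModel(f"{prefix}{i + 1:02d}", glen, region=region,
                                offset=start, intron_lengths=introns))
    return models


def default_plan(seed: int) -> SyntheticPlan:
    """Full-scale plan emulating the published Olyreae plastome dimensions."""
    return build_plan(seed)


def small_plan(seed: int, taxa: int = 4, **overrides) -> SyntheticPlan:
    """Down-scaled plan (LSC 5 kb, IR 2 kb, SSC 1 kb) for fast tests."""
    return build_plan(seed, lsc_len=5000, ssc_len=1000, ir_len=2000,
                      taxa=taxa, n_lsc_genes=4, n_ssc_genes=1,
                      n_mono_ssrs=3, n_di_ssrs=1, n_tri_ssrs=1, n_forward=3,
                      n_palindromic=2, n_reverse=1, n_complement=1,
                      **overrides)


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

class _Builder:
    """Mutable genome buffer that keeps IRb == revcomp(IRa) under edits."""

    def __init__(self, plan: SyntheticPlan, rng: np.random.Generator):
        self.plan = plan
        self.rng = rng
        l, r, s = plan.lsc_len, plan.ir_len, plan.ssc_len
        self.l, self.r, self.s = l, r, s
        self.n = plan.genome_length
        self.b = l + r  # JSB
        self.c = l + r + s  # JSA
        gc = plan.gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=self.n, p=p)
        self.buf = bytearray(bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]))
        self._mirror_all()
        self.protected = np.zeros(self.n, dtype=bool)

    def _mirror(self, x: int) -> int | None:
        if self.l <= x < self.b or self.c <= x < self.n:
            return (self.n + self.l) - 1 - x
        return None

    def _mirror_all(self) -> None:
        ira = bytes(self.buf[self.c : self.n]).decode()
        self.buf[self.l : self.b] = revcomp(ira).encode()

    def set_base(self, x: int, ch: str) -> None:
        self.buf[x] = ord(ch)
        m = self._mirror(x)
        if m is not None:
            self.buf[m] = ord(complement(ch))

    def base(self, x: int) -> str:
        return chr(self.buf[x])

    def write(self, start: int, s: str, protect: bool = True) -> None:
        for t, ch in enumerate(s):
            if self.protected[start + t]:
                raise ValueError(
                    f"planted elements collide at position {start + t}")
            self.set_base(start + t, ch)
        if protect:
            self.protected[start : start + len(s)] = True
            m = self._mirror(start)
            if m is not None:
                self.protected[m - len(s) + 1 : m + 1] = True

    def pick_base(self, forbidden: set[str]) -> str:
        choices = [b for b in _BASES if b not in forbidden]
        return choices[int(self.rng.integers(0, len(choices)))]

    def ensure_differs(self, x: int, forbidden: set[str]) -> None:
        """Make sure base at x is not one of ``forbidden`` (guard base)."""
        if self.base(x) in forbidden:
            if self.protected[x]:
                raise ValueError(f"cannot place guard base at protected {x}")
            self.set_base(x, self.pick_base(forbidden))

    def genome(self, gid: str = "ancestor") -> CircularGenome:
        return CircularGenome(gid, bytes(self.buf).decode())


def _region_start(builder: _Builder, region: str) -> int:
    return {"LSC": 0, "SSC": builder.b, "IR": builder.c}[region]


def _junction_pos(builder: _Builder, junction: str) -> int:
    return {"JLA": 0, "JLB": builder.l, "JSB": builder.b,
            "JSA": builder.c}[junction]


def _gene_interval(builder: _Builder, model: GeneModel) -> tuple[int, int]:
    total = model.length + sum(model.intron_lengths)
    if model.junction is not None:
        start = (_junction_pos(builder, model.junction) + model.offset) % builder.n
    elif model.region is not None:
        start = (_region_start(builder, model.region) + model.offset) % builder.n
    else:
        raise ValueError(f"gene {model.name}: needs region or junction anchor")
    return start, total


def _gene_parts(start: int, model: GeneModel, n: int) -> tuple[Interval, ...]:
    n_exons = len(model.intron_lengths) + 1
    exon_len = model.length // n_exons
    lens: list[int] = []
    for i in range(n_exons):
        el = exon_len if i < n_exons - 1 else model.length - exon_len * (n_exons - 1)
        lens.append(el)
        if i < len(model.intron_lengths):
            lens.append(model.intron_lengths[i])
    parts = []
    pos = start
    for i, ln in enumerate(lens):
        if i % 2 == 0:  # exon
            parts.append(make_interval(pos, ln, n))
        pos += ln
    return tuple(parts)


def _junction_truth(models: Sequence[GeneModel], builder: _Builder,
                    ) -> list[JunctionGeneRecord]:
    """Expected spanning/nearest gene per junction, from plan geometry only."""
    per_junction: dict[str, list[tuple[str, int, int]]] = {j: [] for j in
                                                           ("JLB", "JSB", "JSA",
                                                            "JLA")}
    mirror_of = {"JLA": "JLB", "JLB": "JLA", "JSB": "JSA", "JSA": "JSB"}
    for m in models:
        if m.junction is None:
            continue
        total = m.length + sum(m.intron_lengths)
        per_junction[m.junction].append((m.name, m.offset, total))
        # a gene wholly inside the IRa (anchored upstream of JLA) has a
        # mirrored copy just downstream of the mirror junction JLB
        if m.junction == "JLA" and m.offset + total <= 0 and \
                -m.offset <= builder.r:
            per_junction["JLB"].append((m.name, -(m.offset + total), total))
    records: list[JunctionGeneRecord] = []
    for j, entries in per_junction.items():
        spanning = sorted(name for name, o, t in entries if o < 0 < o + t)
        if spanning:
            records += [JunctionGeneRecord(j, g, "spans", 0) for g in spanning]
            continue
        ups = [(-(o + t), name) for name, o, t in entries if o + t <= 0]
        downs = [(o, name) for name, o, t in entries if o >= 0]
        if ups:
            d, name = min(ups)
            records.append(JunctionGeneRecord(j, name, "upstream", d))
        if downs:
            d, name = min(downs)
            records.append(JunctionGeneRecord(j, name, "downstream", d))
    return records


_REPEAT_TRANSFORM = {
    "forward": lambda s: s,
    "palindromic": revcomp,
    "reverse": lambda s: s[::-1],
    "complement": complement,
}


def generate_ancestor(plan: SyntheticPlan) -> tuple[CircularGenome,
                                                    list[GeneFeature],
                                                    GroundTruth]:
    """Build the ancestral genome, its annotation, and the ground-truth ledger."""
    rng = np.random.default_rng([plan.seed, 11])
    builder = _Builder(plan, rng)
    n = builder.n

    # --- genes -------------------------------------------------------------
    features: list[GeneFeature] = []
    for model in plan.gene_models:
        start, total = _gene_interval(builder, model)
        if model.region == "IR" and start + total > n:
            raise ValueError(f"gene {model.name} exceeds IRa capacity")
        parts = _gene_parts(start, model, n)
        features.append(GeneFeature(model.name, model.kind, model.strand, parts))
        # genes wholly inside the IRa get a mirrored IRb copy
        env_start, env_end = start, start + total
        if builder.c <= env_start and env_end <= n:
            ms = (n + builder.l) - env_end
            mirror_parts = tuple(sorted(
                (make_interval((n + builder.l) - (p.start + p.span(n)),
                               p.span(n), n) for p in parts),
            key=lambda p: p.start))
            strand = "-" if model.strand == "+" else "+"
            features.append(GeneFeature(model.name, model.kind, strand,
                                        mirror_parts))

    # --- planted SSRs -------------------------------------------------------
    ssr_truth: list[SSRHit] = []
    for p in plan.planted_ssrs:
        if p.region not in ("LSC", "SSC"):
            raise ValueError("planted SSRs must lie in LSC or SSC")
        u = len(p.motif)
        if p.copies < MIN_COPIES.get(u, 5):
            raise ValueError(f"planted SSR {p.motif} below detection threshold")
        start = _region_start(builder, p.region) + p.offset
        run = p.motif * p.copies
        end = start + len(run)
        if p.region == "LSC" and end > builder.l:
            raise ValueError(f"planted SSR at {start} exceeds LSC capacity")
        if p.region == "SSC" and end > builder.c:
            raise ValueError(f"planted SSR at {start} exceeds SSC capacity")
        builder.write(start, run)
        ssr_truth.append(SSRHit(canonical_rotation(p.motif), u, p.copies,
                                Interval(start, end)))

    # --- planted dispersed repeats ------------------------------------------
    repeat_truth: list[RepeatHit] = []
    for p in plan.planted_repeats:
        if p.rtype not in _REPEAT_TRANSFORM:
            raise ValueError(f"unknown repeat type {p.rtype}")
        s1 = _region_start(builder, p.region1) + p.offset1
        s2 = _region_start(builder, p.region2) + p.offset2
        if s1 >= s2:
            raise ValueError("planted repeat copies must be ordered (pos1 < pos2)")
        seg = "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=p.length))
        builder.write(s1, seg)
        builder.write(s2, _REPEAT_TRANSFORM[p.rtype](seg))
        repeat_truth.append(RepeatHit(p.rtype, Interval(s1, s1 + p.length),
                                      Interval(s2, s2 + p.length), p.length))

    # --- guard bases: keep planted elements maximal --------------------------
    for hit in ssr_truth:
        a, e = hit.locus.start, hit.locus.end
        u = hit.unit
        if a - 1 >= 0:
            builder.ensure_differs(a - 1, {builder.base(a - 1 + u)})
        if e < n:
            builder.ensure_differs(e, {builder.base(e - u)})
    for hit in repeat_truth:
        p1, p2, L = hit.pos1.start, hit.pos2.start, hit.length
        if hit.rtype == "forward":
            pairs = [((p2 - 1), {builder.base(p1 - 1)}),
                     ((p2 + L), {builder.base(p1 + L)})]
        elif hit.rtype == "complement":
            pairs = [((p2 - 1), {complement(builder.base(p1 - 1))}),
                     ((p2 + L), {complement(builder.base(p1 + L))})]
        elif hit.rtype == "palindromic":
            pairs = [((p2 + L), {complement(builder.base(p1 - 1))}),
                     ((p2 - 1), {complement(builder.base(p1 + L))})]
        else:  # reverse
            pairs = [((p2 + L), {builder.base(p1 - 1)}),
                     ((p2 - 1), {builder.base(p1 + L)})]
        for x, forbidden in pairs:
            if 0 <= x < n:
                builder.ensure_differs(x, forbidden)

    # --- IR maximality guards: the IR pair must not extend ------------------
    builder.ensure_differs(builder.l - 1, {complement(builder.base(0))})
    builder.ensure_differs(builder.b, {complement(builder.base(builder.c - 1))})

    # --- screen accidental repeats/SSRs -------------------------------------
    structure = structure_from_plan(plan)
    _screen(builder, plan, structure, ssr_truth, repeat_truth)

    genome = builder.genome()
    truth = GroundTruth(
        junctions={"JLB": builder.l, "JSB": builder.b, "JSA": builder.c,
                   "JLA": 0},
        region_lengths={"LSC": plan.lsc_len, "IRb": plan.ir_len,
                        "SSC": plan.ssc_len, "IRa": plan.ir_len},
        junction_genes=_junction_truth(plan.gene_models, builder),
        ssrs=ssr_truth, repeats=repeat_truth)
    prot = np.flatnonzero(np.diff(np.concatenate(
        ([0], builder.protected.astype(np.int8), [0]))))
    truth.planted_intervals = [(int(s), int(e))
                               for s, e in zip(prot[::2], prot[1::2])]
    return genome, features, truth


def _touches_protected(builder: _Builder, iv: Interval) -> bool:
    return bool(builder.protected[iv.start : iv.end].any())


def _screen(builder: _Builder, plan: SyntheticPlan,
            structure: QuadripartiteStructure, ssr_truth: list[SSRHit],
            repeat_truth: list[RepeatHit], max_rounds: int = 12) -> None:
    """Break accidental repeats >= screen_len and accidental SSRs by point
    edits outside the planted elements (IR edits are mirrored).

    Hits touching planted intervals are consequences of the planted elements
    themselves (an SSR array is also a short-period forward repeat; a poly-A
    next to a poly-T is a palindromic pair, and such hits may lawfully extend
    a base or two into their flanks) and are left alone — the ground-truth
    ledger records the planted intervals so tests can account for them.
    """
    planted_repeats = {(h.rtype, h.pos1.start, h.pos2.start, h.length)
                       for h in repeat_truth}
    planted_ssrs = {(h.locus.start, h.unit) for h in ssr_truth}
    for _ in range(max_rounds):
        genome = builder.genome()
        offenders: list[Interval] = []
        secondary: list[Interval] = []
        for h in find_repeats(genome, min_repeat_len=plan.screen_len,
                              structure=structure):
            if h.is_ir_pair:
                continue
            if (h.rtype, h.pos1.start, h.pos2.start, h.length) in planted_repeats:
                continue
            if _touches_protected(builder, h.pos1) or \
                    _touches_protected(builder, h.pos2):
                continue
            offenders.append(h.pos2)
            secondary.append(h.pos1)
        for s in find_ssrs(genome):
            if (s.locus.start, s.unit) in planted_ssrs:
                continue
            if _touches_protected(builder, s.locus):
                continue
            offenders.append(s.locus)
            secondary.append(s.locus)
        if not offenders:
            return
        for iv, alt in zip(offenders, secondary):
            _break_interval(builder, iv) or _break_interval(builder, alt)
    raise RuntimeError("could not screen out accidental repeats; adjust plan")


def _break_interval(builder: _Builder, iv: Interval) -> bool:
    """Mutate one unprotected base near (but never exactly at) the middle.

    The exact symmetric center is skipped: for a hit between an IR segment
    and its own mirror image, a center edit is reproduced by the mirrored
    complement edit and leaves the relation intact.
    """
    mid = (iv.start + iv.end) // 2
    order = sorted(range(iv.start, iv.end), key=lambda x: abs(x - mid))
    for x in order:
        if 2 * x == iv.start + iv.end - 1:
            continue
        if not builder.protected[x]:
            builder.set_base(x, builder.pick_base({builder.base(x)}))
            return True
    return False


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _star_newick(k: int) -> str:
    leaves = ",".join(f"t{i:02d}:1.0" for i in range(1, k + 1))
    return f"({leaves});"


def evolve_taxa(genome: CircularGenome, features: Sequence[GeneFeature],
                truth: GroundTruth, plan: SyntheticPlan,
                ) -> list[tuple[CircularGenome, list[GeneFeature]]]:
    """Evolve the ancestor into ``plan.taxa`` annotated genomes.

    Jukes-Cantor substitutions are applied per site along every branch at the
    locus-specific rate (per-branch per-site substitution probability =
    locus rate x branch length, capped below 0.75); the IRb is rebuilt from
    the IRa after every branch so the inverted-repeat identity is exact.
    Optional per-taxon junction shifts move the JSB by the requested number
    of bases (IR expansion into the SSC for positive shifts).
    """
    import dendropy

    rng = np.random.default_rng([plan.seed, 23])
    n = genome.length
    l, r, s = plan.lsc_len, plan.ir_len, plan.ssc_len
    b, c = l + r, l + r + s

    structure = structure_from_plan(plan)
    loci, _ = extract_loci(genome, list(features), structure,
                           min_len=plan.locus_min_len)

    # per-position substitution rate
    rate = np.full(n, plan.background_rate, dtype=float)
    locus_rates: dict[str, float] = {}
    for lx in sorted(loci, key=lambda lx: lx.locus.name):
        if plan.locus_rates and lx.locus.name in plan.locus_rates:
            p = float(plan.locus_rates[lx.locus.name])
        else:
            lo, hi = (plan.coding_rate_range if lx.locus.lclass == "coding"
                      else plan.noncoding_rate_range)
            p = float(rng.uniform(lo, hi))
        locus_rates[lx.locus.name] = p
        for seg in lx.segments:
            if seg.wraps:
                rate[seg.start :] = p
                rate[: seg.end] = p
            else:
                rate[seg.start : seg.end] = p
    rate[l:b] = 0.0  # IRb is rebuilt from IRa, never mutated directly

    newick = plan.tree_newick or _star_newick(plan.taxa)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    root_codes = np.array([_CODE[ch] for ch in genome.seq.encode()],
                          dtype=np.int8)

    leaf_seqs: dict[str, np.ndarray] = {}

    def _mutate(codes: np.ndarray, elen: float) -> np.ndarray:
        p = np.minimum(rate * elen, 0.749)
        hit = rng.random(n) < p
        out = codes.copy()
        idx = np.flatnonzero(hit)
        if idx.size:
            out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
        # co-evolve the IR: rebuild IRb from IRa
        out[l:b] = (3 - out[c:n])[::-1]
        return out

    def _walk(node, codes):
        for child in node.child_nodes():
            elen = child.edge.length if child.edge.length is not None else 1.0
            child_codes = _mutate(codes, float(elen))
            if child.is_leaf():
                label = (child.taxon.label if child.taxon is not None
                         else f"t{len(leaf_seqs) + 1:02d}")
                leaf_seqs[label.replace(" ", "_")] = child_codes
            else:
                _walk(child, child_codes)

    _walk(tree.seed_node, root_codes)
    truth.locus_rates = locus_rates
    truth.tree_newick = newick
    truth.shifts = dict(plan.junction_shifts)

    out: list[tuple[CircularGenome, list[GeneFeature]]] = []
    for label in sorted(leaf_seqs):
        codes = leaf_seqs[label]
        seq = bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]).decode()
        feats = list(features)
        shift = plan.junction_shifts.get(label, 0)
        if shift:
            seq, feats = _apply_jsb_shift(seq, feats, shift, l, r, s, rng)
        out.append((CircularGenome(label, seq), feats))
    return out


def _apply_jsb_shift(seq: str, feats: list[GeneFeature], d: int, l: int,
                     r: int, s: int, rng: np.random.Generator,
                     ) -> tuple[str, list[GeneFeature]]:
    """Move the IRb/SSC junction by ``d`` bases (IR expansion if d > 0)."""
    n = len(seq)
    b, c = l + r, l + r + s
    if d > 0:
        if d >= s:
            raise ValueError("JSB expansion would consume the whole SSC")
        x = seq[b : b + d]
        new_seq = seq[:c] + revcomp(x) + seq[c:]
        feats2 = [_remap_feature(f, c, d, n) for f in feats]
        # guard: the expanded IR must not extend further by chance
        new_seq = _fix_inner_guard(new_seq, l, r + d, s - d)
        return new_seq, [f for f in feats2 if f is not None]
    dd = -d
    if dd >= r:
        raise ValueError("JSB contraction would consume the whole IR")
    new_seq = seq[:c] + seq[c + dd :]
    feats2 = [_remap_feature(f, c, -dd, n, deleted=(c, c + dd)) for f in feats]
    new_seq = _fix_inner_guard(new_seq, l, r - dd, s + dd)
    return new_seq, [f for f in feats2 if f is not None]


def _fix_inner_guard(seq: str, l: int, r: int, s: int) -> str:
    """Ensure the IR pair cannot extend across the new JSB/JSA junctions."""
    b, c = l + r, l + r + s
    if seq[b] == complement(seq[c - 1]):
        for base in _BASES:
            if base != seq[c - 1] and complement(base) != seq[b - 0] and \
                    base != complement(seq[b]):
                return seq[: c - 1] + base + seq[c:]
    return seq


def _remap_feature(f: GeneFeature, pivot: int, delta: int, n: int,
                   deleted: tuple[int, int] | None = None,
                   ) -> GeneFeature | None:
    parts = []
    for p in f.parts:
        s, e = p.start, p.end
        if deleted is not None:
            ds, de = deleted
            if s >= ds and e <= de:
                return None  # feature removed with the deleted IR segment
            if s >= de:
                s, e = s + delta, e + delta
            elif e > ds:
                e = max(ds, e + delta) if e >= de else ds  # truncate
        else:
            if s >= pivot:
                s, e = s + delta, e + delta
            elif e > pivot:
                e += delta  # spans the insertion point
        parts.append(Interval(s, e))
    return replace(f, parts=tuple(parts))


# ---------------------------------------------------------------------------
# convenience: full synthetic cohort
# ---------------------------------------------------------------------------

def generate_cohort(plan: SyntheticPlan):
    """Ancestor + evolved taxa + ground truth in one call."""
    genome, features, truth = generate_ancestor(plan)
    taxa = evolve_taxa(genome, features, truth, plan)
    return genome, features, truth, taxa
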