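"""Per-locus variability statistics and marker selection.

Each homologous locus set is multiple-aligned (deterministic center-star with
affine gaps; a pre-computed alignment can be supplied instead), then scored:

* NS ("variable characters", VCs): alignment columns containing at least two
  distinct bases from {A,C,G,T}.  Gaps and N carry no state, so columns that
  vary only by gaps/N are not variable.
* PICs (parsimony-informative characters): columns with at least two states
  each present in at least two rows.
* percentage statistics: (NS / L) x 100 and (PIC / L) x 100, where L is the
  aligned length including gap columns, rounded half-up to two decimals.

Markers are ranked by percent VCs (ties: percent PICs, then name).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .locus_extract import LocusDef, LocusSet

logger = logging.getLogger(__name__)

_BASES = frozenset(b"ACGT")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (printed-table convention), e.g. 0.125 -> 0.13."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LocusAlignment:
    locus: LocusDef
    rows: Mapping[str, str]  # taxon -> aligned sequence over {A,C,G,T,N,-}
    length_range: tuple[int, int]  # unaligned min/max

    @property
    def L(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass(frozen=True)
class VariabilityRecord:
    locus: LocusDef
    length_range: tuple[int, int]
    L: int
    n_vc: int
    pct_vc: float
    n_pic: int
    pct_pic: float


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _merge_center_star(center: str, pairwise: list[tuple[str, str, str]],
                       ) -> dict[str, str]:
    """Merge pairwise alignments against the center ("once a gap, always a gap").

    ``pairwise`` holds (taxon, center_gapped, other_gapped) strings.  The
    master gap profile takes, before each center position (and at the end),
    the maximum number of inserted columns over all pairwise alignments.
    """
    m = len(center)
    master = np.zeros(m + 1, dtype=int)
    per_aln_gaps: list[np.ndarray] = []
    for _, cg, _og in pairwise:
        gaps = np.zeros(m + 1, dtype=int)
        p = 0
        for ch in cg:
            if ch == "-":
                gaps[p] += 1
            else:
                p += 1
        assert p == m, "center row does not reproduce the center sequence"
        per_aln_gaps.append(gaps)
        master = np.maximum(master, gaps)

    rows: dict[str, str] = {}
    # center row under the master profile
    out = []
    for p in range(m):
        out.append("-" * master[p])
        out.append(center[p])
    out.append("-" * master[m])
    rows["__center__"] = "".join(out)

    for (taxon, cg, og), gaps in zip(pairwise, per_aln_gaps):
        out = []
        p = 0  # center position
        pending = []  # other-row chars inserted before center position p
        for cch, och in zip(cg, og):
            if cch == "-":
                pending.append(och)
            else:
                out.append("".join(pending)
                           + "-" * (master[p] - len(pending)))
                out.append(och)
                pending = []
                p += 1
        out.append("".join(pending) + "-" * (master[m] - len(pending)))
        rows[taxon] = "".join(out)
    return rows


def align_locus(locus_set: LocusSet, match: float = 1, mismatch: float = -1,
                gap_open: float = -4, gap_extend: float = -1,
                ) -> LocusAlignment:
    """Deterministic center-star multiple alignment of one locus set.

    The center is the sequence maximizing the summed pairwise alignment score
    (ties broken by taxon name); all others are aligned pairwise to it and
    merged under a common gap profile.
    """
    seqs = dict(sorted(locus_set.seqs.items()))
    if len(seqs) < 2:
        raise ValueError(f"locus {locus_set.locus.name}: need >= 2 sequences")
    for taxon, s in seqs.items():
        if not s:
            raise ValueError(f"locus {locus_set.locus.name}: empty sequence "
                             f"for {taxon}")
    lengths = [len(s) for s in seqs.values()]
    if len(set(seqs.values())) == 1:
        return LocusAlignment(locus_set.locus, seqs,
                              (min(lengths), max(lengths)))

    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    taxa = list(seqs)
    totals = {t: 0.0 for t in taxa}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            s = aligner.score(seqs[t1], seqs[t2])
            totals[t1] += s
            totals[t2] += s
    # deterministic center choice: highest total, then lexicographically first
    best = max(totals.values())
    center_taxon = sorted(t for t in taxa if totals[t] == best)[0]
    center = seqs[center_taxon]

    pairwise = []
    for taxon in taxa:
        if taxon == center_taxon:
            continue
        aln = aligner.align(center, seqs[taxon])[0]
        pairwise.append((taxon, str(aln[0]), str(aln[1])))
    merged = _merge_center_star(center, pairwise)
    rows = {center_taxon: merged.pop("__center__")}
    rows.update(merged)
    rows = dict(sorted(rows.items()))
    aln_obj = LocusAlignment(locus_set.locus, rows, (min(lengths), max(lengths)))
    validate_alignment(aln_obj, seqs)
    return aln_obj


def validate_alignment(alignment: LocusAlignment,
                       inputs: Mapping[str, str] | None = None) -> None:
    """Check equal row lengths and (optionally) gap-stripped round-trip."""
    lengths = {len(r) for r in alignment.rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"locus {alignment.locus.name}: aligned rows have "
                         f"unequal lengths {sorted(lengths)}")
    if inputs is not None:
        for taxon, row in alignment.rows.items():
            if row.replace("-", "") != inputs[taxon]:
                raise ValueError(f"locus {alignment.locus.name}: row for "
                                 f"{taxon} does not reproduce its input")


def prealigned(locus_set_or_def, rows: Mapping[str, str]) -> LocusAlignment:
    """Wrap an externally computed alignment (validated, used as-is)."""
    locus = (locus_set_or_def.locus if isinstance(locus_set_or_def, LocusSet)
             else locus_set_or_def)
    lengths = [len(r.replace("-", "")) for r in rows.values()]
    aln = LocusAlignment(locus, dict(sorted(rows.items())),
                         (min(lengths), max(lengths)))
    validate_alignment(aln)
    return aln


# ---------------------------------------------------------------------------
# variable / parsimony-informative characters
# ---------------------------------------------------------------------------

def _rows_matrix(alignment: LocusAlignment) -> np.ndarray:
    rows = [np.frombuffer(r.encode(), dtype=np.uint8)
            for r in alignment.rows.values()]
    return np.vstack(rows)


def count_vc(alignment: LocusAlignment) -> int:
    """Number of columns with >= 2 distinct bases among {A,C,G,T}."""
    mat = _rows_matrix(alignment)
    counts = _base_counts(mat)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def count_pic(alignment: LocusAlignment) -> int:
    """Columns with >= 2 distinct bases each occurring in >= 2 rows."""
    mat = _rows_matrix(alignment)
    counts = _base_counts(mat)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """Per-column occurrence counts of A, C, G, T (gaps/N carry no state)."""
    return np.stack([(mat == b).sum(axis=0) for b in b"ACGT"])


# ---------------------------------------------------------------------------
# variability table and marker selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariabilityResult:
    records: pd.DataFrame
    class_summary: pd.DataFrame
    noncoding_coding_ratio: float | None


def variability_record(alignment: LocusAlignment) -> VariabilityRecord:
    L = alignment.L
    ns = count_vc(alignment)
    pic = count_pic(alignment)
    return VariabilityRecord(alignment.locus, alignment.length_range, L, ns,
                             round_half_up(100 * ns / L, 2), pic,
                             round_half_up(100 * pic / L, 2))


def variability_table(alignments: Sequence[LocusAlignment]) -> VariabilityResult:
    """Per-locus records plus per-class (coding/non-coding) summaries.

    The class mean of percent VCs is the unweighted mean over loci; the
    non-coding/coding ratio of those means is reported to one decimal.
    """
    if not alignments:
        raise ValueError("variability_table requires >= 1 alignment")
    recs = [variability_record(a) for a in alignments]
    records = pd.DataFrame([{
        "locus": r.locus.name, "class": r.locus.lclass, "region": r.locus.region,
        "length_min": r.length_range[0], "length_max": r.length_range[1],
        "aligned_length": r.L, "n_vc": r.n_vc, "pct_vc": r.pct_vc,
        "n_pic": r.n_pic, "pct_pic": r.pct_pic,
    } for r in recs])

    rows = []
    means: dict[str, float] = {}
    for lclass, grp in records.groupby("class"):
        mean = round_half_up(float(grp["pct_vc"].mean()), 2)
        means[lclass] = mean
        rows.append({"class": lclass, "n_loci": len(grp),
                     "min_pct_vc": grp["pct_vc"].min(),
                     "max_pct_vc": grp["pct_vc"].max(),
                     "mean_pct_vc": mean})
    summary = pd.DataFrame(rows)
    ratio = None
    if "coding" in means and "noncoding" in means and means["coding"] > 0:
        ratio = noncoding_coding_ratio(means["noncoding"], means["coding"])
    return VariabilityResult(records, summary, ratio)


def noncoding_coding_ratio(mean_noncoding: float, mean_coding: float) -> float:
    """Ratio of class-mean percent VCs, rounded half-up to one decimal."""
    return round_half_up(mean_noncoding / mean_coding, 1)


def select_markers(records: pd.DataFrame, lclass: str = "noncoding",
                   top_n: int | None = 20,
                   min_pct_vc: float | None = None) -> pd.DataFrame:
    """Rank candidate marker loci by percent VCs (descending).

    Ties broken by percent PICs (descending) then locus name, making the
    selection invariant to input order.
    """
    sel = records[records["class"] == lclass].copy()
    if min_pct_vc is not None:
        sel = sel[sel["pct_vc"] > min_pct_vc]
    sel = sel.sort_values(["pct_vc", "pct_pic", "locus"],
                          ascending=[False, False, True], kind="mergesort")
    if top_n is not None:
        if top_n > len(sel):
            logger.warning("requested top %d markers but only %d available",
                           top_n, len(sel))
        sel = sel.head(top_n)
    return sel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sliding-window percent identity
# ---------------------------------------------------------------------------

def sliding_identity(rows: Mapping[str, str], reference: str,
                     window: int = 100, step: int = 25,
                     min_comparable: int = 10) -> pd.DataFrame:
    """mVISTA-style per-window percent identity of each row to the reference.

    Identity in a window = 100 x (matching positions) / (positions where both
    the row and the reference have a base).  Windows with fewer than
    ``min_comparable`` comparable positions get NaN.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if window < 10:
        raise ValueError("window must be >= 10")
    if reference not in rows:
        raise ValueError(f"reference {reference!r} not among rows")
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError("rows must be aligned (equal lengths)")
    L = lengths.pop()
    ref = np.frombuffer(rows[reference].encode(), dtype=np.uint8)
    is_base_ref = np.isin(ref, np.frombuffer(b"ACGT", dtype=np.uint8))
    out = []
    starts = range(0, max(L - window, 0) + 1, step)
    for taxon in sorted(rows):
        if taxon == reference:
            continue
        row = np.frombuffer(rows[taxon].encode(), dtype=np.uint8)
        is_base = np.isin(row, np.frombuffer(b"ACGT", dtype=np.uint8))
        comparable = is_base_ref & is_base
        matches = comparable & (ref == row)
        ccum = np.concatenate(([0], np.cumsum(comparable)))
        mcum = np.concatenate(([0], np.cumsum(matches)))
        for s in starts:
            e = s + window
            nc = ccum[e] - ccum[s]
            nm = mcum[e] - mcum[s]
            ident = round_half_up(100 * nm / nc, 2) if nc >= min_comparable \
                else float("nan")
            out.append({"taxon": taxon, "start": s, "end": e,
                        "identity": ident})
    return pd.DataFrame(out, columns=["taxon", "start", "end", "identity"])
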