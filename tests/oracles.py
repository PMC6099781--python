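"""Independent brute-force oracles used to validate the scanners and counters.

These deliberately take the slow exhaustive route (all diagonals / all
positions / all columns) so they share no code with the seed-and-extend and
vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# dispersed repeats: exhaustive diagonal / anti-diagonal scan
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop-exclusive) index pairs."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def repeat_oracle(seq: str, min_len: int) -> dict[str, set[tuple[int, int, int]]]:
    """All maximal repeat hits per type as (start1, start2, length) triples."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_map = np.zeros(256, dtype=np.uint8)
    for a, b in _COMP.items():
        comp_map[ord(a)] = ord(b)
    carr = comp_map[arr]
    valid = arr != ord("N")
    n = len(arr)
    out: dict[str, set] = {t: set() for t in
                           ("forward", "palindromic", "reverse", "complement")}

    for d in range(1, n):
        v = valid[:-d] & valid[d:]
        for mask, t in (((arr[:-d] == arr[d:]) & v, "forward"),
                        ((arr[d:] == carr[:-d]) & v, "complement")):
            for i0, i1 in _runs(mask):
                if i1 - i0 >= min_len:
                    out[t].add((int(i0), int(i0 + d), int(i1 - i0)))

    for c in range(2 * n - 1):
        lo, hi = max(0, c - n + 1), min(c, n - 1)
        ys = np.arange(lo, hi + 1)
        xs = c - ys
        v = valid[ys] & valid[xs]
        for mask, t in (((arr[ys] == carr[xs]) & v, "palindromic"),
                        ((arr[ys] == arr[xs]) & v, "reverse")):
            for i0, i1 in _runs(mask):
                y0, y1 = int(ys[i0]), int(ys[i1 - 1])
                L = y1 - y0 + 1
                if L >= min_len and y0 + y1 > c:
                    out[t].add((c - y1, y0, L))
    return out


# ---------------------------------------------------------------------------
# SSRs: naive per-position walk
# ---------------------------------------------------------------------------

def _aperiodic(motif: str) -> bool:
    u = len(motif)
    return not any(u % p == 0 and motif == motif[:p] * (u // p)
                   for p in range(1, u))


def ssr_oracle(seq: str, min_copies: dict[int, int]) -> set[tuple[int, int, int]]:
    """All maximal tandem arrays as (locus_start, unit, copies) triples."""
    n = len(seq)
    hits: set[tuple[int, int, int]] = set()
    for u in range(1, 7):
        a = 0
        while a + u <= n:
            motif = seq[a : a + u]
            if "N" in motif or not _aperiodic(motif):
                a += 1
                continue
            # left-maximality: the array must not extend one char to the left
            if a - 1 >= 0 and seq[a - 1] != "N" and seq[a - 1] == seq[a + u - 1]:
                a += 1
                continue
            b = a + u
            while b < n and seq[b] != "N" and seq[b] == seq[b - u]:
                b += 1
            copies = (b - a) // u
            if copies >= min_copies.get(u, 5):
                hits.add((a, u, copies))
            a += 1
    return hits


# ---------------------------------------------------------------------------
# per-column variability
# ---------------------------------------------------------------------------

def vc_pic_oracle(rows: list[str]) -> tuple[int, int]:
    vc = pic = 0
    for col in zip(*rows):
        states: dict[str, int] = {}
        for ch in col:
            if ch in "ACGT":
                states[ch] = states.get(ch, 0) + 1
        if len(states) >= 2:
            vc += 1
            if sum(1 for v in states.values() if v >= 2) >= 2:
                pic += 1
    return vc, pic


# ---------------------------------------------------------------------------
# tiny exhaustive pairwise aligner (affine gaps, first-gap-char = open)
# ---------------------------------------------------------------------------

def exhaustive_pair_score(s1: str, s2: str, match=1, mismatch=-1,
                          gap_open=-4, gap_extend=-1) -> float:
    """Optimal global alignment score by exhaustive enumeration (tiny inputs).

    Gap runs are charged gap_open for the first gapped position and
    gap_extend for every further one, matching the scoring used by the
    production aligner.
    """
    best = [-np.inf]

    def rec(i, j, score, prev):
        if i == len(s1) and j == len(s2):
            best[0] = max(best[0], score)
            return
        # bound: even all-matches cannot beat best
        if score + min(len(s1) - i, len(s2) - j) + 0 < best[0] - 20:
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1,
                score + (match if s1[i] == s2[j] else mismatch), "m")
        if i < len(s1):
            rec(i + 1, j, score + (gap_extend if prev == "d" else gap_open), "d")
        if j < len(s2):
            rec(i, j + 1, score + (gap_extend if prev == "i" else gap_open), "i")

    rec(0, 0, 0.0, "m")
    return float(best[0])


def alignment_score(row1: str, row2: str, match=1, mismatch=-1, gap_open=-4,
                    gap_extend=-1) -> float:
    """Score of a given pairwise alignment under the same convention."""
    score = 0.0
    prev = "m"
    for a, b in zip(row1, row2):
        if a == "-" or b == "-":
            kind = "d" if b == "-" else "i"
            score += gap_extend if prev == kind else gap_open
            prev = kind
        else:
            score += match if a == b else mismatch
            prev = "m"
    return score


# ---------------------------------------------------------------------------
# star-tree column variability expectation
# ---------------------------------------------------------------------------

def expected_pct_variable(p: float, k: int) -> float:
    """Closed-form probability (in %) that a star-tree column is variable.

    Each of k taxa independently keeps the ancestral base w.p. 1-p or takes a
    specific other base w.p. p/3; a column is variable unless all taxa agree.
    """
    p_const = (1 - p) ** k + 3 * (p / 3) ** k
    return 100 * (1 - p_const)
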