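"""Independent brute-force oracles used by the test-suite.

Everything here is written from first principles with plain loops, separate
from the package implementations it checks.
"""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb
from typing import Dict, List, Sequence, Set, Tuple

Exons = List[Tuple[int, int]]


# ---------------------------------------------------------------------------
# Fisher's exact test: exact rational enumeration over margin-fixed tables
# ---------------------------------------------------------------------------

def fisher_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating every table with the same margins,
    using exact rational hypergeometric probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(min(Fraction(1), total))


# ---------------------------------------------------------------------------
# Greedy poly(A) clustering: step-by-step trace with explicit scans
# ---------------------------------------------------------------------------

def cluster_trace(
    counts: Dict[int, int], halfwidth: int, separation: int
) -> List[Tuple[int, int]]:
    """Re-derivation of the greedy clustering used for cleavage positions.

    Selection: repeatedly scan for the highest-count unconsumed position
    (ties to the lowest coordinate), absorb everything within +/- halfwidth.
    Pruning: walk representatives in selection order; one that lies within
    ``separation`` of an already-kept representative is merged into the
    closest kept one (ties: larger pre-merge count, then lower coordinate).
    """
    todo = dict(counts)
    picked: List[Tuple[int, int]] = []  # (rep, absorbed count) in pick order
    while todo:
        best = None
        for pos, cnt in todo.items():
            if best is None or cnt > todo[best] or (cnt == todo[best] and pos < best):
                best = pos
        absorbed = 0
        for pos in list(todo):
            if abs(pos - best) <= halfwidth:
                absorbed += todo.pop(pos)
        picked.append((best, absorbed))
    kept: List[List[int]] = []  # [rep, current count, original count]
    for rep, cnt in picked:
        near = [k for k in kept if abs(k[0] - rep) <= separation]
        if near:
            near.sort(key=lambda k: (abs(k[0] - rep), -k[2], k[0]))
            near[0][1] += cnt
        else:
            kept.append([rep, cnt, cnt])
    return sorted((rep, cnt) for rep, cnt, _ in kept)


# ---------------------------------------------------------------------------
# AS events: exhaustive pairwise enumeration over plain exon lists
# ---------------------------------------------------------------------------

def _introns(exons: Exons) -> List[Tuple[int, int]]:
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def _overlap(x: Tuple[int, int], y: Tuple[int, int]) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def enumerate_pair_events(
    name1: str, exons1: Exons, name2: str, exons2: Exons, strand: str
) -> Set[Tuple[str, Tuple[int, ...], str, str]]:
    """All (type, coords, inclusion transcript, exclusion transcript) tuples
    for one transcript pair, enumerated exhaustively."""
    found: Set[Tuple[str, Tuple[int, ...], str, str]] = set()
    pairs = [(name1, exons1, name2, exons2), (name2, exons2, name1, exons1)]

    # RI: look at every exon of A and every intron (with flanks) of B
    for na, ea, nb, eb in pairs:
        ib = _introns(eb)
        for (xs, xe) in ea:
            for i, (b, c) in enumerate(ib):
                if eb[i][0] == xs and eb[i + 1][1] == xe:
                    found.add(("RI", (xs, b, c, xe), na, nb))

    # SE: internal exon of A absent from B, which joins the flanks directly
    for na, ea, nb, eb in pairs:
        ia, ib = _introns(ea), set(_introns(eb))
        for i in range(1, len(ea) - 1):
            b = ia[i - 1][0]
            e = ia[i][1]
            if (b, e) in ib:
                found.add(("SE", (b, ea[i][0], ea[i][1], e), na, nb))

    # A5/A3: one shared intron boundary, variable-side exons overlapping
    i1, i2 = _introns(exons1), _introns(exons2)
    for (b1, c1) in i1:
        for (b2, c2) in i2:
            if c1 == c2 and b1 != b2:
                left1 = next(e for e in exons1 if e[1] == b1)
                left2 = next(e for e in exons2 if e[1] == b2)
                if _overlap(left1, left2):
                    etype = "A5" if strand == "+" else "A3"
                    inc, exc = (name1, name2) if b1 > b2 else (name2, name1)
                    found.add((etype, (min(b1, b2), max(b1, b2), c1), inc, exc))
            if b1 == b2 and c1 != c2:
                right1 = next(e for e in exons1 if e[0] == c1)
                right2 = next(e for e in exons2 if e[0] == c2)
                if _overlap(right1, right2):
                    etype = "A3" if strand == "+" else "A5"
                    inc, exc = (name1, name2) if c1 < c2 else (name2, name1)
                    found.add((etype, (b1, min(c1, c2), max(c1, c2)), inc, exc))

    # AF/AL: non-overlapping terminal exons with a shared inner splice site
    if len(exons1) >= 2 and len(exons2) >= 2:
        def add_terminal(etype, t1_exon, t2_exon, shared_ok, boundary, inc_first):
            if t1_exon != t2_exon and not _overlap(t1_exon, t2_exon) and shared_ok:
                lo, hi = sorted([t1_exon, t2_exon])
                if etype in ("AF",) and strand == "+" or etype in ("AL",) and strand == "-":
                    coords = lo + hi + (boundary,)
                else:
                    coords = (boundary,) + lo + hi
                inc, exc = (name1, name2) if inc_first else (name2, name1)
                found.add((etype, coords, inc, exc))

        if strand == "+":
            add_terminal(
                "AF", exons1[0], exons2[0], i1[0][1] == i2[0][1], i1[0][1],
                exons1[0][0] < exons2[0][0],
            )
            add_terminal(
                "AL", exons1[-1], exons2[-1], i1[-1][0] == i2[-1][0], i1[-1][0],
                exons1[-1][1] > exons2[-1][1],
            )
        else:
            add_terminal(
                "AF", exons1[-1], exons2[-1], i1[-1][0] == i2[-1][0], i1[-1][0],
                exons1[-1][1] > exons2[-1][1],
            )
            add_terminal(
                "AL", exons1[0], exons2[0], i1[0][1] == i2[0][1], i1[0][1],
                exons1[0][0] < exons2[0][0],
            )

    # MX: consecutive intron pairs sharing outer boundaries, middles disjoint
    for ai in range(len(i1) - 1):
        for bi in range(len(i2) - 1):
            b, c1 = i1[ai]
            d1, e = i1[ai + 1]
            b2, c2 = i2[bi]
            d2, e2 = i2[bi + 1]
            if b != b2 or e != e2:
                continue
            m1, m2 = (c1, d1), (c2, d2)
            if m1 == m2 or _overlap(m1, m2):
                continue
            lo, hi = sorted([m1, m2])
            coords = (b,) + lo + hi + (e,)
            if strand == "+":
                inc_first = m1 < m2
            else:
                inc_first = m1 > m2
            inc, exc = (name1, name2) if inc_first else (name2, name1)
            found.add(("MX", coords, inc, exc))

    return found


def enumerate_gene_events(
    isoforms: Dict[str, Exons], strand: str
) -> Dict[Tuple[str, Tuple[int, ...]], Tuple[Set[str], Set[str]]]:
    """Deduplicated event map: (type, coords) -> (inclusion, exclusion sets)."""
    merged: Dict[Tuple[str, Tuple[int, ...]], Tuple[Set[str], Set[str]]] = {}
    names = sorted(isoforms)
    for na, nb in itertools.combinations(names, 2):
        for etype, coords, inc, exc in enumerate_pair_events(
            na, isoforms[na], nb, isoforms[nb], strand
        ):
            key = (etype, coords)
            if key not in merged:
                merged[key] = (set(), set())
            merged[key][0].add(inc)
            merged[key][1].add(exc)
    return merged


def random_isoform_gene(rng, max_isoforms: int = 5, max_exons: int = 8):
    """Random multi-isoform gene on a coarse boundary grid (shared splice
    sites arise frequently). Returns (isoforms dict, strand)."""
    strand = "+" if rng.random() < 0.5 else "-"
    grid = [10 * k for k in range(1, 41)]
    n_iso = int(rng.integers(2, max_isoforms + 1))
    isoforms: Dict[str, Exons] = {}
    for k in range(n_iso):
        n_exons = int(rng.integers(2, max_exons + 1))
        boundaries = sorted(rng.choice(len(grid), size=2 * n_exons, replace=False))
        coords = [grid[i] for i in boundaries]
        exons = [(coords[2 * i], coords[2 * i + 1]) for i in range(n_exons)]
        isoforms[f"iso{k}"] = exons
    return isoforms, strand


# ---------------------------------------------------------------------------
# Permutation test: bitmask enumeration of label assignments
# ---------------------------------------------------------------------------

def permutation_p_bruteforce(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    pooled = list(group_a) + list(group_b)
    n, n_a = len(pooled), len(group_a)
    obs = sum(group_b) / len(group_b) - sum(group_a) / n_a
    hits = total = 0
    for mask in range(1 << n):
        if bin(mask).count("1") != n_a:
            continue
        total += 1
        a = [pooled[i] for i in range(n) if mask >> i & 1]
        b = [pooled[i] for i in range(n) if not mask >> i & 1]
        delta = sum(b) / len(b) - sum(a) / len(a)
        if abs(delta) >= abs(obs) - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Small maximum bipartite matcher for recovery-score checks
# ---------------------------------------------------------------------------

def max_matching_size(
    true_positions: Sequence[int], called_positions: Sequence[int], tolerance: int
) -> int:
    """Maximum one-to-one matching size by exhaustive recursive search."""
    called = list(called_positions)

    def rec(i: int, used: frozenset) -> int:
        if i == len(true_positions):
            return 0
        best = rec(i + 1, used)  # leave this true site unmatched
        for j, c in enumerate(called):
            if j not in used and abs(c - true_positions[i]) <= tolerance:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())
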