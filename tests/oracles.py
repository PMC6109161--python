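"""Independent brute-force oracles used to check the package's algorithms.

These deliberately avoid the implementation paths they verify: plain
dynamic programming, exhaustive scans and string-level breadth-first
search, practical only at test scale.
"""

from __future__ import annotations

import re
from itertools import product

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def edit_distance_and_min_gaps(a: str, b: str) -> tuple[int, int]:
    """(minimum edit distance, fewest gaps among minimum-edit alignments)."""
    n, m = len(a), len(b)
    # DP over (edit cost, gap count), compared lexicographically
    prev = [(j, j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i, i)]
        for j in range(1, m + 1):
            sub = (prev[j - 1][0] + (a[i - 1] != b[j - 1]), prev[j - 1][1])
            dele = (prev[j][0] + 1, prev[j][1] + 1)
            ins = (cur[j - 1][0] + 1, cur[j - 1][1] + 1)
            cur.append(min(sub, dele, ins))
        prev = cur
    return prev[m]


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def conserved_runs(rows: list[str]) -> list[tuple[int, int]]:
    """(start, length) of maximal columns identical across equal-length rows."""
    n = len(rows[0])
    assert all(len(r) == n for r in rows)
    runs = []
    start = None
    for col in range(n + 1):
        ok = col < n and len({r[col] for r in rows}) == 1 and rows[0][col] != "-"
        if ok and start is None:
            start = col
        elif not ok and start is not None:
            runs.append((start, col - start))
            start = None
    return runs


def shufflon_string_closure(sequence: str, motif: str, max_states: int = 100_000) -> set[str]:
    """All sequences reachable by flips between opposite-orientation motifs.

    Works purely on strings: motif occurrences are located by scanning,
    and a flip reverse-complements the span between the inner edges of an
    oppositely oriented occurrence pair.
    """
    rcm = rc(motif)
    assert motif != rcm

    def occurrences(s: str) -> list[tuple[int, str]]:
        occ = []
        for needle, orient in ((motif, "+"), (rcm, "-")):
            for m in re.finditer(f"(?={re.escape(needle)})", s):
                occ.append((m.start(), orient))
        occ.sort()
        return occ

    seen = {sequence}
    frontier = [sequence]
    while frontier:
        nxt = []
        for s in frontier:
            occ = occurrences(s)
            for i in range(len(occ)):
                for j in range(i + 1, len(occ)):
                    if occ[i][1] == occ[j][1]:
                        continue
                    a_end = occ[i][0] + len(motif)
                    b_start = occ[j][0]
                    if b_start < a_end:
                        continue
                    flipped = s[:a_end] + rc(s[a_end:b_start]) + s[b_start:]
                    if flipped not in seen:
                        assert len(seen) < max_states
                        seen.add(flipped)
                        nxt.append(flipped)
        frontier = nxt
    return seen


def tir_tsd_bruteforce(
    insertion: str, left: str, right: str, max_mismatch: int
) -> tuple[int, int]:
    """Quadratic-scan terminal-inverted-repeat / target-site-duplication."""
    best_tir = 0
    for t in range(1, len(insertion) // 2 + 1):
        mm = hamming(insertion[:t], rc(insertion[-t:]))
        if mm <= max_mismatch:
            best_tir = max(best_tir, t)
    best_tsd = 0
    for d in range(1, min(len(left), len(right)) + 1):
        if left[-d:] == right[:d]:
            best_tsd = max(best_tsd, d)
    return best_tir, best_tsd


def shared_unique_kmers(a: str, b: str, k: int) -> set[str]:
    """k-mers occurring exactly once in a and once in b (both strands of b)."""
    def counts(s: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            out[s[i : i + k]] = out.get(s[i : i + k], 0) + 1
        return out

    ca, cb = counts(a), counts(b)
    out = set()
    for km, n in ca.items():
        if n != 1:
            continue
        tot = cb.get(km, 0) + (0 if rc(km) == km else cb.get(rc(km), 0))
        if tot == 1:
            out.add(km)
    return out
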