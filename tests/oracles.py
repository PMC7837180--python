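"""Independent reference implementations used only by the test suite.

These deliberately avoid the production code paths: the local-alignment
oracles use a different DP formulation (general gap costs, max over gap
length) and a brute-force enumeration of move sequences; the global
oracle enumerates every alignment of two short sequences.
"""

from __future__ import annotations

import numpy as np

from phylocore.orthology import encode


def sw_wsb(a: str, b: str, S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Waterman–Smith–Beyer local alignment: general gap penalty evaluated by
    an explicit max over gap lengths (O(nm(n+m)))."""
    ea, eb = encode(a), encode(b)
    n, m = len(ea), len(eb)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v = H[i - 1, j - 1] + S[ea[i - 1], eb[j - 1]]
            for k in range(1, i + 1):
                v = max(v, H[i - k, j] - (gap_open + k * gap_extend))
            for k in range(1, j + 1):
                v = max(v, H[i, j - k] - (gap_open + k * gap_extend))
            v = max(v, 0.0)
            H[i, j] = v
            best = max(best, v)
    return best


def global_enum(a: str, b: str, S: np.ndarray, gap_open: float,
                gap_extend: float) -> float:
    """Best global alignment score by enumerating every move sequence.

    A gap of length k costs gap_open + k*gap_extend; terminal gaps are
    penalized.  Exponential — keep sequences short (<= ~6)."""
    ea, eb = encode(a), encode(b)
    best = [-np.inf]

    def rec(i: int, j: int, score: float, state: str) -> None:
        if i == len(ea) and j == len(eb):
            best[0] = max(best[0], score)
            return
        if i < len(ea) and j < len(eb):
            rec(i + 1, j + 1, score + S[ea[i], eb[j]], "M")
        if i < len(ea):
            cost = gap_extend if state == "A" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "A")
        if j < len(eb):
            cost = gap_extend if state == "B" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "B")

    rec(0, 0, 0.0, "M")
    return best[0]


def sw_enum(a: str, b: str, S: np.ndarray, gap_open: float,
            gap_extend: float) -> float:
    """Local alignment score by enumerating global alignments of every
    substring pair (gap-terminal variants only score lower, so the max over
    substring pairs is the local optimum).  Exponential — tiny inputs only."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_enum(a[i1:i2], b[j1:j2],
                                                 S, gap_open, gap_extend))
    return best


def pairwise_p_count(a: str, b: str) -> tuple[int, int]:
    """(differences, compared sites) under pairwise deletion, by direct loop."""
    diff = comp = 0
    for x, y in zip(a, b):
        if x in "-X" or y in "-X":
            continue
        comp += 1
        if x != y:
            diff += 1
    return diff, comp
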