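"""Dynamic-programming alignment kernels.

Affine gap convention throughout: a gap of length k costs
``gap_open + k * gap_extend``; the first gapped position therefore costs
``gap_open + gap_extend`` and each further position ``gap_extend``.
Local alignment (Smith–Waterman) floors cell scores at zero; global
alignment (Needleman–Wunsch over profile column scores) penalizes
terminal gaps like internal ones.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=False)
def sw_score_kernel(a: np.ndarray, b: np.ndarray, S: np.ndarray,
                    gap_open: float, gap_extend: float) -> float:
    """Smith–Waterman local alignment score (Gotoh three-state recurrence)."""
    n = a.shape[0]
    m = b.shape[0]
    H_prev = np.zeros(m + 1)
    F = np.full(m + 1, NEG_INF)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        H_cur = np.zeros(m + 1)
        E = NEG_INF
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(H_cur[j - 1] - first, E - gap_extend)
            F[j] = max(H_prev[j] - first, F[j] - gap_extend)
            h = H_prev[j - 1] + S[ai, b[j - 1]]
            h = max(h, E)
            h = max(h, F[j])
            if h < 0.0:
                h = 0.0
            H_cur[j] = h
            if h > best:
                best = h
        H_prev = H_cur
    return best


@njit(cache=False)
def nw_profile_kernel(M: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine alignment over a precomputed column-score matrix ``M``.

    ``M[i, j]`` is the score of aligning column i of the first profile with
    column j of the second.  Returns (score, traceback) where traceback
    codes 0 = diagonal, 1 = gap in second profile (consume i), 2 = gap in
    first profile (consume j), per DP state.
    """
    n, m = M.shape
    first = gap_open + gap_extend
    H = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in first profile (moves j)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in second profile (moves i)
    tb = np.zeros((n + 1, m + 1, 3), dtype=np.uint8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -first - gap_extend * (j - 1)
        H[0, j] = E[0, j]
        tb[0, j, 0] = 2
        tb[0, j, 1] = 1  # E extends E
    for i in range(1, n + 1):
        F[i, 0] = -first - gap_extend * (i - 1)
        H[i, 0] = F[i, 0]
        tb[i, 0, 0] = 1
        tb[i, 0, 2] = 1  # F extends F
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - first
            ee = E[i, j - 1] - gap_extend
            if ee > eo:
                E[i, j] = ee
                tb[i, j, 1] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] - first
            fe = F[i - 1, j] - gap_extend
            if fe > fo:
                F[i, j] = fe
                tb[i, j, 2] = 1
            else:
                F[i, j] = fo
            d = H[i - 1, j - 1] + M[i - 1, j - 1]
            h = d
            code = 0
            if F[i, j] > h:
                h = F[i, j]
                code = 1
            if E[i, j] > h:
                h = E[i, j]
                code = 2
            H[i, j] = h
            tb[i, j, 0] = code
    return H[n, m], tb


def traceback_path(tb: np.ndarray, n: int, m: int) -> list[tuple[int, int]]:
    """Recover the aligned column pairs from ``nw_profile_kernel`` traceback.

    Yields (i, j) pairs, −1 marking a gap, ordered left to right.
    """
    path: list[tuple[int, int]] = []
    i, j = n, m
    state = 0  # 0 = H, 1 = F (gap in second), 2 = E (gap in first)
    while i > 0 or j > 0:
        if state == 0:
            state = tb[i, j, 0]
            if state == 0:
                path.append((i - 1, j - 1))
                i -= 1
                j -= 1
        elif state == 1:
            path.append((i - 1, -1))
            cont = tb[i, j, 2]
            i -= 1
            state = 1 if cont else 0
        else:
            path.append((-1, j - 1))
            cont = tb[i, j, 1]
            j -= 1
            state = 2 if cont else 0
    path.reverse()
    return path


def global_affine_align(M: np.ndarray, gap_open: float, gap_extend: float
                        ) -> tuple[float, list[tuple[int, int]]]:
    """Score and aligned column pairs for a profile-profile global alignment."""
    score, tb = nw_profile_kernel(np.ascontiguousarray(M, dtype=np.float64),
                                  float(gap_open), float(gap_extend))
    return float(score), traceback_path(tb, M.shape[0], M.shape[1])
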