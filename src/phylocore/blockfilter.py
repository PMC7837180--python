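"""Conserved-block selection over a super-alignment (Gblocks-style).

Columns are first classified by conservation level, then blocks are
selected by four ordered rules: gap columns (and nonconserved runs
touching them) are removed, long nonconserved stretches are removed,
surviving segments are trimmed back to highly-conserved flanks, and
short segments are dropped.  The default parameter arithmetic for N
sequences pins the published defaults explicitly, including rounding
direction: IS = floor(N/2)+1, FS = ceil(0.85·N), CP = 8, BL = 10, no
gaps allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .msa import GAP
from .supermatrix import SuperAlignment


class Status(str, Enum):
    GAP = "g"
    NONCONSERVED = "N"
    CONSERVED = "C"
    HIGHLY_CONSERVED = "H"


@dataclass(frozen=True)
class BlockFilterParams:
    min_conserved: int            # IS: residues that must agree for "conserved"
    min_flank: int                # FS: agreement needed for "highly conserved"
    max_contig_nonconserved: int = 8   # CP
    min_block_length: int = 10         # BL
    allow_gaps: str = "none"

    def __post_init__(self) -> None:
        if self.min_conserved > self.min_flank:
            raise ValueError("min_conserved must not exceed min_flank")
        if self.max_contig_nonconserved < 1 or self.min_block_length < 2:
            raise ValueError("invalid stretch/length parameters")
        if self.allow_gaps not in ("none", "half", "all"):
            raise ValueError("allow_gaps must be none|half|all")

    @classmethod
    def defaults(cls, n_sequences: int) -> "BlockFilterParams":
        if n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        return cls(min_conserved=n_sequences // 2 + 1,
                   min_flank=math.ceil(0.85 * n_sequences))

    def validate_for(self, n_sequences: int) -> None:
        if not (n_sequences / 2 < self.min_conserved <= self.min_flank <= n_sequences):
            raise ValueError(
                f"require N/2 < IS <= FS <= N for N={n_sequences} "
                f"(IS={self.min_conserved}, FS={self.min_flank})")


def classify_columns(sa: SuperAlignment, params: BlockFilterParams) -> str:
    """Per-column status string over {g, N, C, H}.

    With ``allow_gaps='none'`` any gap makes the column a gap column;
    otherwise the most frequent residue count c sets the level:
    c < IS → nonconserved, c ≥ FS → highly conserved, else conserved.
    X counts as its own residue (it never boosts another residue's count).
    """
    n = len(sa.rows)
    params.validate_for(n)
    out = []
    for i in range(sa.length):
        col = sa.column(i)
        n_gaps = col.count(GAP)
        gappy = (n_gaps > 0 if params.allow_gaps == "none"
                 else n_gaps > n // 2 if params.allow_gaps == "half"
                 else False)
        if gappy:
            out.append(Status.GAP.value)
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        c_max = max(counts.values())
        if c_max < params.min_conserved:
            out.append(Status.NONCONSERVED.value)
        elif c_max >= params.min_flank:
            out.append(Status.HIGHLY_CONSERVED.value)
        else:
            out.append(Status.CONSERVED.value)
    return "".join(out)


def _runs(status: str, symbol: str) -> list[tuple[int, int]]:
    """Maximal runs of ``symbol``, half-open."""
    runs = []
    i = 0
    while i < len(status):
        if status[i] == symbol:
            j = i
            while j < len(status) and status[j] == symbol:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def select_blocks(status: str, params: BlockFilterParams) -> list[tuple[int, int]]:
    """Retained column ranges (0-based, half-open) after the four rules.

    1. Remove gap columns and every nonconserved run adjacent to one.
    2. Remove nonconserved runs longer than ``max_contig_nonconserved``.
    3. Trim each surviving segment to its outermost highly-conserved columns.
    4. Drop segments shorter than ``min_block_length``.
    An empty result is legal.
    """
    L = len(status)
    removed = np.zeros(L, dtype=bool)
    # rule 1: gaps plus adjacent nonconserved runs
    gap_cols = [i for i, s in enumerate(status) if s == Status.GAP.value]
    removed[gap_cols] = True
    for start, end in _runs(status, Status.NONCONSERVED.value):
        left_gap = start > 0 and status[start - 1] == Status.GAP.value
        right_gap = end < L and status[end] == Status.GAP.value
        if left_gap or right_gap:
            removed[start:end] = True
    # rule 2: long nonconserved stretches
    for start, end in _runs(status, Status.NONCONSERVED.value):
        if end - start > params.max_contig_nonconserved:
            removed[start:end] = True
    # segments of surviving columns
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if removed[i]:
            i += 1
            continue
        j = i
        while j < L and not removed[j]:
            j += 1
        # rule 3: trim to highly conserved flanks
        a, b = i, j
        while a < b and status[a] != Status.HIGHLY_CONSERVED.value:
            a += 1
        while b > a and status[b - 1] != Status.HIGHLY_CONSERVED.value:
            b -= 1
        # rule 4: minimum block length
        if b - a >= params.min_block_length:
            blocks.append((a, b))
        i = j
    return blocks


def apply_filter(sa: SuperAlignment, params: BlockFilterParams | None = None
                 ) -> list[tuple[int, int]]:
    """Classify, select blocks, and write the retention mask into ``sa``."""
    if params is None:
        params = BlockFilterParams.defaults(len(sa.rows))
    status = classify_columns(sa, params)
    blocks = select_blocks(status, params)
    mask = np.zeros(sa.length, dtype=bool)
    for a, b in blocks:
        mask[a:b] = True
    sa.retained_mask = mask
    return blocks


def report_text(status: str, blocks: Sequence[tuple[int, int]]) -> str:
    """Human-readable report: status string, a '.'/'*' retention track, and
    retained ranges in 1-based inclusive coordinates."""
    track = ["."] * len(status)
    for a, b in blocks:
        for i in range(a, b):
            track[i] = "*"
    lines = [status, "".join(track), ""]
    lines += [f"block {k + 1}: {a + 1}-{b}" for k, (a, b) in enumerate(blocks)]
    return "\n".join(lines) + "\n"
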