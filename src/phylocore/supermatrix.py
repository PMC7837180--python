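"""Concatenation of per-group alignments into one super-alignment.

Partition bookkeeping records which column range came from which
ortholog group; a per-column boolean retention mask (set later by the
conserved-block filter) travels with the matrix.  Missing strains are a
hard error — core-group construction guarantees full occupancy, so a gap
here is a pipeline bug, not data to be padded over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msa import GAP, Alignment


class SupermatrixError(ValueError):
    pass


@dataclass
class SuperAlignment:
    rows: list[tuple[str, str]]                      # (strain_id, concatenated row)
    partitions: list[tuple[str, int, int]]           # (group_id, start, end) half-open
    retained_mask: np.ndarray = field(default=None)  # bool per column

    def __post_init__(self) -> None:
        if not self.rows:
            raise SupermatrixError("super-alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise SupermatrixError("rows differ in length")
        (self.length,) = lengths
        pos = 0
        for gid, start, end in self.partitions:
            if start != pos or end <= start:
                raise SupermatrixError(f"partition {gid} does not tile the alignment")
            pos = end
        if pos != self.length:
            raise SupermatrixError("partitions do not cover the alignment")
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.length, dtype=bool)
        else:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
            if self.retained_mask.shape != (self.length,):
                raise SupermatrixError("retained mask length mismatch")

    @property
    def strain_ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def column(self, i: int) -> list[str]:
        return [s[i] for _, s in self.rows]

    def retained_columns(self) -> int:
        return int(self.retained_mask.sum())


def concatenate(alignments: Sequence[tuple[str, Alignment]]) -> SuperAlignment:
    """Append alignments column-wise in list order, recording partitions.

    All alignments must cover an identical strain set; row order follows
    the first alignment.
    """
    if not alignments:
        raise SupermatrixError("nothing to concatenate")
    first_gid, first = alignments[0]
    strain_order = first.strain_ids
    strain_set = set(strain_order)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {sid: [] for sid in strain_order}
    pos = 0
    for gid, aln in alignments:
        if set(aln.strain_ids) != strain_set:
            missing = (strain_set ^ set(aln.strain_ids))
            raise SupermatrixError(
                f"group {gid!r}: strain set mismatch (offending strains: {sorted(missing)})")
        for sid in strain_order:
            chunks[sid].append(aln.row(sid))
        parts.append((gid, pos, pos + aln.length))
        pos += aln.length
    rows = [(sid, "".join(chunks[sid])) for sid in strain_order]
    return SuperAlignment(rows, parts)


def count_variable_sites(sa: SuperAlignment, respect_mask: bool = True) -> int:
    """Columns with at least two distinct non-gap, non-X residues.

    Gaps and ambiguity codes never create variability, so the count is
    invariant to gap coding.
    """
    count = 0
    for i in range(sa.length):
        if respect_mask and not sa.retained_mask[i]:
            continue
        residues = {c for c in sa.column(i) if c not in (GAP, "X")}
        if len(residues) >= 2:
            count += 1
    return count
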