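"""Genome composition tracks: GC content and windowed GC skew.

GC skew, (G − C)/(G + C) per window, is the standard strand-asymmetry
diagnostic for bacterial chromosomes: the sign typically flips at the
replication origin and terminus.  The chromosome is treated as linear
(no wraparound window); windows tile the sequence without overlap and
the last window may be short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: per-window skew when the window contains no G or C
UNDEFINED_SKEW = math.nan

DEFAULT_WINDOW = 10_000


@dataclass
class SkewProfile:
    window_size: int
    values: list[tuple[int, float]]  # (0-based window start, skew or NaN)
    cumulative: list[float]          # running sum, NaN windows skipped

    def __len__(self) -> int:
        return len(self.values)


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T); ambiguous bases excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    g = seq.count("G")
    c = seq.count("C")
    a = seq.count("A")
    t = seq.count("T")
    total = a + c + g + t
    if total == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (g + c) / total


def gc_skew_profile(seq: str, window: int = DEFAULT_WINDOW) -> SkewProfile:
    """Non-overlapping windowed GC skew with a cumulative running sum.

    A window with no G or C gets NaN and does not advance the cumulative
    series' running sum.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    values: list[tuple[int, float]] = []
    cumulative: list[float] = []
    running = 0.0
    for start in range(0, len(seq), window):
        chunk = seq[start:start + window]
        g = chunk.count("G")
        c = chunk.count("C")
        if g + c == 0:
            values.append((start, UNDEFINED_SKEW))
        else:
            skew = (g - c) / (g + c)
            values.append((start, skew))
            running += skew
        cumulative.append(running)
    return SkewProfile(window, values, cumulative)


def composition_table(seq: str, window: int = DEFAULT_WINDOW) -> list[dict]:
    """Per-window rows: window_start, gc_content, gc_skew, cumulative_skew."""
    profile = gc_skew_profile(seq, window)
    rows = []
    for (start, skew), cum in zip(profile.values, profile.cumulative):
        chunk = seq[start:start + window]
        try:
            gc = gc_content(chunk)
        except ValueError:
            gc = math.nan
        rows.append({"window_start": start, "gc_content": gc,
                     "gc_skew": skew, "cumulative_skew": cum})
    return rows
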