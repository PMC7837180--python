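"""Reference-anchored reciprocal-best-hit orthology and core-proteome extraction.

One strain serves as the reference; each of its proteins is searched
against every other strain's proteome by exact Smith–Waterman local
alignment (affine gaps, BLOSUM62, open 11 / extend 1 — the classic
protein-search defaults), hits are thresholded on a Karlin–Altschul
E-value, and a protein pair is called orthologous when each is the
other's best hit.  Reference proteins with a reciprocal best hit in
*every* other proteome form the single-copy core used for phylogenomics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._align import sw_score_kernel
from .seqio import Proteome, SequenceRecord

#: residue order used by every encoded matrix; X is the ambiguity state
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine-gap costs and Karlin–Altschul constants.

    ``lam`` (nats per score unit) and ``K`` parametrize the E-value
    E = K·m·n·exp(−lam·S); the defaults are the standard gapped-BLOSUM62
    constants.  A gap of length k costs ``gap_open + k·gap_extend``.
    """

    matrix: np.ndarray  # (21, 21) over ALPHABET, symmetric
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(ALPHABET), len(ALPHABET)) or not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric over the 21-letter alphabet")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @classmethod
    def blosum62(cls, **kwargs) -> "ScoringScheme":
        return cls(matrix=load_matrix("BLOSUM62"), **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "ScoringScheme":
        return cls(matrix=parse_matrix_text(Path(path).read_text()), **kwargs)


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A named substitution matrix restricted to the 21-letter alphabet."""
    raw = substitution_matrices.load(name)
    return _restrict(dict(zip(raw.alphabet, range(len(raw.alphabet)))), np.asarray(raw))


def parse_matrix_text(text: str) -> np.ndarray:
    """Parse NCBI-style substitution matrix text (header row of residues,
    one labelled row per residue)."""
    cols: list[str] = []
    values: dict[str, list[int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not cols:
            cols = fields
        else:
            values[fields[0]] = [int(round(float(v))) for v in fields[1:]]
    lookup = {c: i for i, c in enumerate(cols)}
    full = np.zeros((len(cols), len(cols)), dtype=np.int64)
    for res, row in values.items():
        full[lookup[res], :] = row
    return _restrict(lookup, full)


def _restrict(lookup: dict[str, int], full: np.ndarray) -> np.ndarray:
    out = np.full((len(ALPHABET), len(ALPHABET)), -1, dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a in lookup and b in lookup:
                out[i, j] = int(full[lookup[a], lookup[b]])
    return out


def encode(seq: str) -> np.ndarray:
    """Map a protein string onto alphabet indices."""
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside the protein alphabet") from None


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    score: int
    evalue: float


@dataclass
class OrthologGroup:
    """One reference protein plus its reciprocal best hit in every other strain."""

    reference_protein_id: str
    members: dict[str, str]  # strain_id -> protein_id, reference strain included

    def __len__(self) -> int:
        return len(self.members)


def smith_waterman_score(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> int:
    """Optimal local-alignment score under affine gaps (≥ 0 by the local floor)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme.blosum62()
    score = sw_score_kernel(encode(a), encode(b),
                            scheme.matrix.astype(np.float64),
                            float(scheme.gap_open), float(scheme.gap_extend))
    return int(round(score))


def evalue(score: int, m: int, n: int, scheme: Optional[ScoringScheme] = None) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S)."""
    if score < 0 or m < 1 or n < 1:
        raise ValueError("require score >= 0 and positive sequence lengths")
    scheme = scheme or ScoringScheme.blosum62()
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def best_hit(query: SequenceRecord, target: Proteome,
             scheme: Optional[ScoringScheme] = None,
             e_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> Optional[PairwiseHit]:
    """Highest-scoring target protein passing the E-value cutoff, or None.

    Ties broken toward the lexicographically smaller subject id.
    """
    scheme = scheme or ScoringScheme.blosum62()
    best: Optional[PairwiseHit] = None
    for rec in target.records:
        s = smith_waterman_score(query.residues, rec.residues, scheme)
        e = evalue(s, len(query), len(rec), scheme)
        if e > e_cutoff:
            continue
        if best is None or s > best.score or (s == best.score and rec.id < best.subject_id):
            best = PairwiseHit(query.id, rec.id, s, e)
    return best


def _score_table(ref: Proteome, other: Proteome, scheme: ScoringScheme) -> np.ndarray:
    S = scheme.matrix.astype(np.float64)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    enc_ref = [encode(r.residues) for r in ref.records]
    enc_oth = [encode(r.residues) for r in other.records]
    table = np.empty((len(enc_ref), len(enc_oth)))
    for i, a in enumerate(enc_ref):
        for j, b in enumerate(enc_oth):
            table[i, j] = sw_score_kernel(a, b, S, go, ge)
    return table


def _best_index(scores: Sequence[float], evalues: Sequence[float], ids: Sequence[str],
                e_cutoff: float) -> Optional[int]:
    best = None
    for idx, (s, e) in enumerate(zip(scores, evalues)):
        if e > e_cutoff:
            continue
        if best is None or s > scores[best] or (s == scores[best] and ids[idx] < ids[best]):
            best = idx
    return best


def reciprocal_best_hits(ref: Proteome, other: Proteome,
                         scheme: Optional[ScoringScheme] = None,
                         e_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> dict[str, str]:
    """Mapping ref protein id → other protein id for mutual best hits.

    Scoring is symmetric, so one all-pairs score table serves both search
    directions; the E-value differs per direction only through sequence
    lengths (it does not here, since m·n is symmetric too, but the cutoff
    is applied in both directions for clarity).
    """
    scheme = scheme or ScoringScheme.blosum62()
    table = _score_table(ref, other, scheme)
    ref_ids = ref.ids
    oth_ids = other.ids
    ref_len = [len(r) for r in ref.records]
    oth_len = [len(r) for r in other.records]
    ev = np.array([[scheme.K * ref_len[i] * oth_len[j] * math.exp(-scheme.lam * table[i, j])
                    for j in range(len(oth_ids))] for i in range(len(ref_ids))])
    forward: dict[int, int] = {}
    for i in range(len(ref_ids)):
        j = _best_index(table[i, :], ev[i, :], oth_ids, e_cutoff)
        if j is not None:
            forward[i] = j
    mapping: dict[str, str] = {}
    for i, j in forward.items():
        back = _best_index(table[:, j], ev[:, j], ref_ids, e_cutoff)
        if back == i:
            mapping[ref_ids[i]] = oth_ids[j]
    return mapping


def extract_core_groups(ref: Proteome, others: Sequence[Proteome],
                        scheme: Optional[ScoringScheme] = None,
                        e_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[OrthologGroup]:
    """Ortholog groups for reference proteins with an RBH partner in every
    other proteome, ordered by reference protein id."""
    if not others:
        raise ValueError("need at least one non-reference proteome")
    scheme = scheme or ScoringScheme.blosum62()
    maps = {p.strain_id: reciprocal_best_hits(ref, p, scheme, e_cutoff) for p in others}
    groups: list[OrthologGroup] = []
    for rid in sorted(ref.ids):
        if all(rid in m for m in maps.values()):
            members = {ref.strain_id: rid}
            for strain, m in maps.items():
                members[strain] = m[rid]
            groups.append(OrthologGroup(rid, members))
    return groups
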