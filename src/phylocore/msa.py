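"""Progressive multiple alignment of ortholog groups.

A MUSCLE-style first iteration: pairwise k-mer dissimilarities feed a
UPGMA guide tree, and profiles are merged bottom-up by global
profile–profile alignment (sum-of-pairs BLOSUM62 column scores, affine
gaps, terminal gaps penalized like internal ones).  Iterative refinement
is deliberately out of scope — downstream supermatrix signal, not exact
column identity, is what the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._align import global_affine_align
from .orthology import ALPHABET, ScoringScheme, encode

GAP = "-"
_GAP_CODE = len(ALPHABET)  # 21


class AlignmentError(ValueError):
    pass


@dataclass
class MsaParams:
    """Progressive-alignment knobs: guide-tree word size and profile gap costs.

    Profile gap costs are in score units per sequence pair spanned by the
    gap; half-integer extension costs are allowed at the profile stage.
    """

    k: int = 3
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class Alignment:
    """Equal-length aligned rows keyed by strain, in input order."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise AlignmentError("alignment rows differ in length")
        (self.length,) = lengths
        if self.length < 1:
            raise AlignmentError("alignment has zero columns")
        for col in range(self.length):
            if all(s[col] == GAP for _, s in self.rows):
                raise AlignmentError(f"column {col} is all gaps")

    @property
    def strain_ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def row(self, strain_id: str) -> str:
        for sid, s in self.rows:
            if sid == strain_id:
                return s
        raise KeyError(strain_id)

    def degapped(self, strain_id: str) -> str:
        return self.row(strain_id).replace(GAP, "")


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 − |shared distinct k-mers| / min(distinct k-mers of a, of b)."""
    if len(a) < k or len(b) < k:
        raise AlignmentError(f"sequence shorter than k={k}")
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


@dataclass
class GuideNode:
    """UPGMA cluster: a leaf (label set of size 1) or a merge of two children."""

    label: str          # lexicographically smallest member, used for tie-breaks
    members: frozenset[str]
    height: float = 0.0
    children: tuple["GuideNode", "GuideNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


def build_guide_tree(labels: Sequence[str], d: np.ndarray) -> GuideNode:
    """UPGMA merge order from a symmetric dissimilarity matrix.

    Ties in the minimum pairwise distance are broken toward the
    lexicographically smallest (label, label) pair, so the merge order is
    deterministic.
    """
    n = len(labels)
    if n < 2:
        raise AlignmentError("guide tree needs at least 2 taxa")
    d = np.asarray(d, dtype=float)
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise AlignmentError("guide-tree matrix must be symmetric with zero diagonal")
    clusters = [GuideNode(lab, frozenset([lab])) for lab in labels]
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = d[i, j]
    active = list(range(n))
    nodes: dict[int, GuideNode] = dict(enumerate(clusters))
    sizes = {i: 1 for i in active}
    next_id = n
    while len(active) > 1:
        best_pair = None
        best_key = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                dd = dist[frozenset((a, b))]
                la, lb = sorted((nodes[a].label, nodes[b].label))
                key = (dd, la, lb)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        na, nb = nodes[a], nodes[b]
        left, right = (na, nb) if na.label <= nb.label else (nb, na)
        merged = GuideNode(min(na.label, nb.label), na.members | nb.members,
                           height=best_key[0] / 2.0, children=(left, right))
        nodes[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            dc = (sizes[a] * dist[frozenset((a, c))] + sizes[b] * dist[frozenset((b, c))]) \
                / (sizes[a] + sizes[b])
            dist[frozenset((next_id, c))] = dc
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class _Profile:
    ids: list[str]
    codes: np.ndarray  # (n_rows, length) ints; GAP_CODE for gaps

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def counts(self) -> np.ndarray:
        """(length, 21) residue counts per column; gaps excluded."""
        out = np.zeros((self.length, len(ALPHABET)))
        for row in self.codes:
            mask = row < _GAP_CODE
            np.add.at(out, (np.nonzero(mask)[0], row[mask]), 1.0)
        return out


def _merge_profiles(pa: _Profile, pb: _Profile, scheme: ScoringScheme,
                    params: MsaParams) -> _Profile:
    S = scheme.matrix.astype(np.float64)
    M = pa.counts() @ S @ pb.counts().T
    scale = len(pa.ids) * len(pb.ids)
    _, path = global_affine_align(M, params.gap_open * scale, params.gap_extend * scale)
    cols_a = np.array([i for i, _ in path])
    cols_b = np.array([j for _, j in path])
    new_len = len(path)
    codes = np.full((len(pa.ids) + len(pb.ids), new_len), _GAP_CODE, dtype=np.int64)
    a_pos = cols_a >= 0
    b_pos = cols_b >= 0
    codes[:len(pa.ids)][:, a_pos] = pa.codes[:, cols_a[a_pos]]
    codes[len(pa.ids):][:, b_pos] = pb.codes[:, cols_b[b_pos]]
    return _Profile(pa.ids + pb.ids, codes)


def pairwise_global_score(a: str, b: str, scheme: Optional[ScoringScheme] = None,
                          params: Optional[MsaParams] = None) -> float:
    """Global affine-gap alignment score of two sequences under the profile
    scoring used by the progressive stage."""
    scheme = scheme or ScoringScheme.blosum62()
    params = params or MsaParams()
    S = scheme.matrix.astype(np.float64)
    ea, eb = encode(a), encode(b)
    M = S[np.ix_(ea, eb)]
    score, _ = global_affine_align(M, params.gap_open, params.gap_extend)
    return score


def progressive_align(sequences: dict[str, str] | Sequence[tuple[str, str]],
                      scheme: Optional[ScoringScheme] = None,
                      params: Optional[MsaParams] = None) -> Alignment:
    """Align a group of homologous protein sequences along a UPGMA guide tree.

    Row order in the result equals input order; de-gapping any row
    reproduces the corresponding input exactly.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise AlignmentError("progressive alignment needs at least 2 sequences")
    scheme = scheme or ScoringScheme.blosum62()
    params = params or MsaParams()
    by_id = dict(items)
    if len(by_id) != len(items):
        raise AlignmentError("duplicate strain ids in alignment input")

    labels = [sid for sid, _ in items]
    k_eff = min(params.k, min(len(s) for _, s in items))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(items[i][1], items[j][1], k_eff)
    guide = build_guide_tree(labels, d)

    def align_node(node: GuideNode) -> _Profile:
        if node.is_leaf:
            (lab,) = node.members
            return _Profile([lab], encode(by_id[lab])[None, :])
        left, right = node.children  # type: ignore[misc]
        return _merge_profiles(align_node(left), align_node(right), scheme, params)

    profile = align_node(guide)
    order = {sid: i for i, sid in enumerate(profile.ids)}
    rev = {i: c for i, c in enumerate(ALPHABET)}
    rev[_GAP_CODE] = GAP
    rows = []
    for sid, _ in items:
        codes = profile.codes[order[sid]]
        rows.append((sid, "".join(rev[int(c)] for c in codes)))
    aln = Alignment(rows)
    for sid, original in items:
        if aln.degapped(sid) != original:
            raise AlignmentError(f"alignment corrupted sequence for {sid}")
    return aln
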