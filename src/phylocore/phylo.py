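"""Distance-based tree inference for the core-proteome super-alignment.

Pairwise observed difference proportions (pairwise deletion over the
retained columns; gaps and X never compared) are corrected for multiple
hits with the Kimura protein formula d = −ln(1 − p − 0.2 p²), trees are
built by Saitou–Nei neighbor joining with the Studier–Keppler Q
criterion, and branch support comes from resampling retained columns
with replacement and counting bipartition recovery.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from .supermatrix import SuperAlignment
from .tree import Node, PhyloTree, TreeError, robinson_foulds  # noqa: F401 (re-export)

log = logging.getLogger(__name__)

#: distance assigned when 1 − p − 0.2 p² ≤ 0 (p ≳ 0.854), i.e. saturation
DISTANCE_CAP = 10.0

_CODES = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACDEFGHIKLMNPQRSTVWY"):
    _CODES[ord(_c)] = _i
# gap and X stay -1: excluded from every pairwise comparison


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")
        self.values = v

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for name, row in zip(self.taxa, self.values):
            lines.append(name + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def _encode_rows(sa: SuperAlignment) -> np.ndarray:
    mat = np.empty((len(sa.rows), sa.length), dtype=np.int8)
    for i, (_, row) in enumerate(sa.rows):
        mat[i] = _CODES[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    return mat


def p_distance(row_a: str, row_b: str, mask: np.ndarray | None = None) -> float:
    """Observed difference proportion with pairwise deletion.

    Only columns where both rows carry an unambiguous residue (and the
    mask, if given, retains the column) are compared.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    a = _CODES[np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)]
    b = _CODES[np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)]
    valid = (a >= 0) & (b >= 0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n_comp = int(valid.sum())
    if n_comp == 0:
        raise ValueError("no comparable sites between the two rows")
    return float((a[valid] != b[valid]).sum()) / n_comp


def kimura_correct(p: float | np.ndarray, cap: float = DISTANCE_CAP):
    """Kimura (1983) protein distance d = −ln(1 − p − 0.2 p²), capped when
    the argument of the logarithm is non-positive (saturated pairs)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    arg = 1.0 - arr - 0.2 * arr * arr
    saturated = arg <= 0
    if np.any(saturated):
        log.warning("%d saturated distance(s) capped at %.1f", int(np.sum(saturated)), cap)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(saturated, cap, -np.log(np.where(saturated, 1.0, arg)))
    return float(d) if np.isscalar(p) or np.ndim(p) == 0 else d


def _pairwise_p(mat: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """p-distance matrix over the given column index array."""
    sub = mat[:, cols]
    n = sub.shape[0]
    valid = sub >= 0
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise ValueError(f"no comparable sites between taxa {i} and {j}")
            p[i, j] = p[j, i] = float((sub[i, both] != sub[j, both]).sum()) / n_comp
    return p


def distance_matrix(sa: SuperAlignment, respect_mask: bool = True) -> DistanceMatrix:
    """Kimura-corrected distances over the retained super-alignment columns."""
    if len(sa.rows) < 3:
        raise ValueError("need at least 3 strains")
    cols = np.nonzero(sa.retained_mask)[0] if respect_mask else np.arange(sa.length)
    if cols.size == 0:
        raise ValueError("no retained columns")
    mat = _encode_rows(sa)
    p = _pairwise_p(mat, cols)
    d = kimura_correct(p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sa.strain_ids, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei agglomeration with the Studier–Keppler Q criterion.

    Exact on additive matrices; negative limb-length estimates are clamped
    to zero; Q ties are broken toward the lexicographically smallest pair
    of cluster labels (the smallest leaf name in each cluster), so the
    output is deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.copy()
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_key = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                la, lb = sorted((labels[i], labels[j]))
                key = (q, la, lb)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = Node(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:m - 2, :m - 2] = D[np.ix_(keep, keep)]
        D_new[:m - 2, m - 2] = D_new[m - 2, :m - 2] = new_row[keep]
        D_new[m - 2, m - 2] = 0.0
        D = D_new
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # final 3-node star: closed-form limb lengths
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return PhyloTree(Node(children=[a, b, c]))


def bootstrap_support(sa: SuperAlignment, reference: PhyloTree,
                      replicates: int = 500, seed: int = 0) -> PhyloTree:
    """Column-resampling bootstrap mapped onto the reference topology.

    Each replicate resamples the retained columns with replacement (same
    count), recomputes the distance matrix and an NJ tree; an internal
    edge's support is the percentage of replicate trees containing its
    bipartition.  One seeded generator drives the whole run, so a fixed
    seed fixes every support value.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if len(sa.rows) < 4:
        raise ValueError("bootstrap support is undefined for fewer than 4 taxa")
    cols = np.nonzero(sa.retained_mask)[0]
    if cols.size == 0:
        raise ValueError("no retained columns")
    mat = _encode_rows(sa)
    taxa = sa.strain_ids
    rng = np.random.Generator(np.random.PCG64(seed))
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        sample = rng.choice(cols, size=cols.size, replace=True)
        p = _pairwise_p(mat, sample)
        d = kimura_correct(p)
        np.fill_diagonal(d, 0.0)
        rep = neighbor_joining(DistanceMatrix(taxa, d))
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    out = copy.deepcopy(reference)
    all_leaves = frozenset(out.leaf_names())
    ref_leaf = min(all_leaves)
    clades = out._clades()
    for node in out.root.walk():
        if node is out.root or node.is_leaf:
            continue
        side = clades[id(node)]
        if ref_leaf in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            node.support = 100.0 * counts.get(side, 0) / replicates
    return out
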