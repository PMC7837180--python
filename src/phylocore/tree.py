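"""Unrooted phylogenetic trees with branch lengths and bipartition support.

The container is deliberately small: named leaves, non-negative branch
lengths in substitutions per site, and an optional bootstrap support
percentage attached to each internal edge.  A tree is stored rooted at an
arbitrary node (conventionally a trifurcation for an unrooted tree); all
comparisons go through bipartitions, which are rooting-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class TreeError(ValueError):
    pass


@dataclass
class Node:
    """One tree node; ``length`` is the branch to the parent (0 at the root)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class PhyloTree:
    """A tree over a set of uniquely named leaves.

    Bootstrap support for the edge above an internal node lives on that
    node's ``support`` attribute, as an integer percentage in [0, 100].
    """

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise TreeError("duplicate leaf names in tree")
        for node in root.walk():
            if node.is_leaf and not node.name:
                raise TreeError("tree contains an unnamed leaf")
            if node.length < 0:
                raise TreeError("negative branch length")

    # -- basic accessors ---------------------------------------------------

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self.leaves())

    # -- bipartitions ------------------------------------------------------

    def _clades(self) -> dict[int, frozenset[str]]:
        """Leaf-name set under every node, keyed by id(node)."""
        clades: dict[int, frozenset[str]] = {}

        def rec(node: Node) -> frozenset[str]:
            if node.is_leaf:
                s = frozenset([node.name])  # type: ignore[list-item]
            else:
                s = frozenset().union(*(rec(c) for c in node.children))
            clades[id(node)] = s
            return s

        rec(self.root)
        return clades

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the side *not* containing the
        lexicographically smallest leaf.  Rooting-invariant."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        clades = self._clades()
        splits: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            side = clades[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def bipartition_support(self) -> dict[frozenset[str], float | None]:
        """Support value attached to each non-trivial split."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        clades = self._clades()
        out: dict[frozenset[str], float | None] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = clades[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = node.support
        return out

    # -- metrics -----------------------------------------------------------

    def path_length_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """Leaf-to-leaf path lengths (the tree's additive metric)."""
        # adjacency over node ids
        adj: dict[int, list[tuple[int, float]]] = {}
        nodes: dict[int, Node] = {}
        for node in self.root.walk():
            nodes[id(node)] = node
            adj.setdefault(id(node), [])
            for child in node.children:
                adj[id(node)].append((id(child), child.length))
                adj.setdefault(id(child), []).append((id(node), child.length))
        leaves = sorted(self.leaves(), key=lambda n: n.name)  # type: ignore[arg-type]
        names = [l.name for l in leaves]  # type: ignore[misc]
        dist: list[list[float]] = [[0.0] * len(leaves) for _ in leaves]
        index = {id(l): i for i, l in enumerate(leaves)}
        for i, leaf in enumerate(leaves):
            # Dijkstra is overkill on a tree; simple DFS accumulation
            seen = {id(leaf)}
            stack = [(id(leaf), 0.0)]
            while stack:
                nid, d = stack.pop()
                if nid in index and nid != id(leaf):
                    dist[i][index[nid]] = d
                for other, w in adj[nid]:
                    if other not in seen:
                        seen.add(other)
                        stack.append((other, d + w))
        return names, dist

    def total_length(self) -> float:
        return sum(n.length for n in self.root.walk() if n is not self.root)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        from . import seqio  # local import: seqio owns the format

        return seqio.newick_string(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self)} leaves)"


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson–Foulds) distance between two trees.

    Counts the non-trivial bipartitions present in exactly one tree.
    """
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise TreeError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())
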