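"""Proteome evolution simulator with a known ground-truth tree.

Core genes start as uniform-random root sequences and accumulate
substitutions down a random unrooted binary tree under the uniform
20-state Markov model (the 20-letter analogue of Jukes–Cantor): along a
branch of length b substitutions/site, each site changes with
probability (19/20)(1 − e^(−(20/19)·b)), to a uniformly chosen different
residue.  The closed form makes pairwise divergence exactly predictable,
which is the module's calibration contract.  Each strain additionally
carries lineage-specific decoy genes — fresh random sequences drawn from
the same residue distribution as the roots — so reciprocal-best-hit
rejection is exercised, and protein ids are shuffled per strain so file
order carries no orthology signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import Proteome, SequenceRecord, write_fasta, write_newick
from .tree import Node, PhyloTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class SimConfig:
    n_taxa: int = 12
    n_core_genes: int = 20
    gene_length: int = 200
    n_decoy_genes: int = 5
    tree_depth: float = 0.3      # expected substitutions/site, root to tip
    seed: int = 0
    indel_rate: float = 0.0      # optional stress knob; 0 keeps genes length-aligned

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.gene_length < 20:
            raise ValueError("gene_length must be >= 20")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be positive")


@dataclass
class GroundTruth:
    true_tree: PhyloTree
    ortholog_map: dict[str, dict[str, str]]   # gene id -> strain -> protein id
    decoys: dict[str, list[str]] = field(default_factory=dict)


def expected_p_distance(d: float) -> float:
    """Expected observed difference proportion at path distance d under the
    uniform 20-state model."""
    return (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * d))


def sample_tree(n_taxa: int, tree_depth: float, seed: int) -> PhyloTree:
    """Random unrooted binary topology by sequential addition; exponential
    branch lengths rescaled so the mean root-to-tip path equals tree_depth."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.Generator(np.random.PCG64(seed))
    width = len(str(n_taxa))
    names = [f"S{i + 1:0{width}d}" for i in range(n_taxa)]
    root = Node(children=[Node(name=names[0]), Node(name=names[1]), Node(name=names[2])])
    parents: dict[int, Node] = {id(c): root for c in root.children}
    attachable: list[Node] = list(root.children)
    for name in names[3:]:
        target = attachable[rng.integers(len(attachable))]
        parent = parents[id(target)]
        leaf = Node(name=name)
        mid = Node(children=[target, leaf])
        parent.children[parent.children.index(target)] = mid
        parents[id(mid)] = parent
        parents[id(target)] = mid
        parents[id(leaf)] = mid
        attachable.extend([mid, leaf])
    branches = [n for n in root.walk() if n is not root]
    for node in branches:
        node.length = float(rng.exponential(1.0))
    tree = PhyloTree(root)
    depths = _leaf_depths(root)
    scale = tree_depth / (sum(depths.values()) / len(depths))
    for node in branches:
        node.length *= scale
    return tree


def _leaf_depths(root: Node) -> dict[str, float]:
    depths: dict[str, float] = {}

    def rec(node: Node, acc: float) -> None:
        if node.is_leaf:
            depths[node.name] = acc  # type: ignore[index]
        for c in node.children:
            rec(c, acc + c.length)

    rec(root, 0.0)
    return depths


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return bytes(_AA[rng.integers(0, 20, size=length)]).decode()


def evolve_sequence(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    """One branch of the uniform 20-state process applied to every site."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p_change = expected_p_distance(branch_length)
    hit = rng.random(codes.size) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        current = codes[hit]
        # draw uniformly among the 19 other residues
        offsets = rng.integers(1, 20, size=n_hit)
        idx = np.searchsorted(_AA, current)
        codes[hit] = _AA[(idx + offsets) % 20]
    return bytes(codes).decode()


def _apply_indels(seq: str, branch_length: float, rate: float,
                  rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    if rng.random() < 1.0 - math.exp(-rate * branch_length):
        span = int(rng.geometric(0.5))
        pos = int(rng.integers(0, max(1, len(seq) - span)))
        seq = seq[:pos] + seq[pos + span:]
    return seq


def evolve_proteomes(tree: PhyloTree, cfg: SimConfig
                     ) -> tuple[list[Proteome], GroundTruth]:
    """Evolve cfg.n_core_genes root genes down the tree and add decoys.

    Returns one proteome per leaf plus the ground truth (true tree,
    ortholog map, decoy ids).  Deterministic for a fixed config.
    """
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    gene_ids = [f"g{i + 1:03d}" for i in range(cfg.n_core_genes)]
    roots = {g: random_sequence(cfg.gene_length, rng) for g in gene_ids}

    # evolve every gene along every branch, depth-first from the root
    leaf_genes: dict[str, dict[str, str]] = {}

    def rec(node: Node, state: dict[str, str]) -> None:
        if node.is_leaf:
            leaf_genes[node.name] = state  # type: ignore[index]
            return
        for child in node.children:
            child_state = {}
            for g, seq in state.items():
                evolved = evolve_sequence(seq, child.length, rng)
                child_state[g] = _apply_indels(evolved, child.length, cfg.indel_rate, rng)
            rec(child, child_state)

    rec(tree.root, dict(roots))

    proteomes: list[Proteome] = []
    ortholog_map: dict[str, dict[str, str]] = {g: {} for g in gene_ids}
    decoys: dict[str, list[str]] = {}
    for strain in sorted(leaf_genes):
        genes = leaf_genes[strain]
        entries: list[tuple[str | None, str]] = [(g, genes[g]) for g in gene_ids]
        for _ in range(cfg.n_decoy_genes):
            entries.append((None, random_sequence(cfg.gene_length, rng)))
        order = rng.permutation(len(entries))
        records = []
        decoys[strain] = []
        for slot, k in enumerate(order):
            gene, seq = entries[k]
            pid = f"{strain}_p{slot + 1:03d}"
            records.append(SequenceRecord(pid, seq))
            if gene is None:
                decoys[strain].append(pid)
            else:
                ortholog_map[gene][strain] = pid
        proteomes.append(Proteome(strain, records))
    return proteomes, GroundTruth(tree, ortholog_map, decoys)


def simulate_dataset(cfg: SimConfig) -> tuple[list[Proteome], GroundTruth]:
    """Sample a tree and evolve proteomes in one call."""
    tree = sample_tree(cfg.n_taxa, cfg.tree_depth, cfg.seed)
    return evolve_proteomes(tree, cfg)


def write_simulation(proteomes: list[Proteome], truth: GroundTruth,
                     outdir: str | Path) -> None:
    """Per-strain FASTA, true-tree Newick, and a ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in proteomes:
        write_fasta(p.records, outdir / f"{p.strain_id}.faa")
    write_newick(truth.true_tree, outdir / "true_tree.nwk")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("gene_id\tstrain_id\tprotein_id\n")
        for g in sorted(truth.ortholog_map):
            for strain in sorted(truth.ortholog_map[g]):
                fh.write(f"{g}\t{strain}\t{truth.ortholog_map[g][strain]}\n")
        for strain in sorted(truth.decoys):
            for pid in truth.decoys[strain]:
                fh.write(f"decoy\t{strain}\t{pid}\n")
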