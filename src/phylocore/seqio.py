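"""FASTA and Newick input/output.

Sequence records carry an id (first whitespace-delimited token of the
header), a free-text description, and uppercased residues validated
against either the 20-letter amino-acid alphabet (plus ``X``) or the
nucleotide alphabet ``ACGT`` (plus ``N``).  Stop characters ``*`` in
protein sequences are stripped with a warning, as proteome exports
commonly include them.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .tree import Node, PhyloTree, TreeError

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Proteome:
    """All annotated protein sequences of one strain."""

    strain_id: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError(f"proteome {self.strain_id!r} has no records")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceError(f"duplicate record id {dup!r} in proteome {self.strain_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, protein_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == protein_id:
                return r
        raise KeyError(protein_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _validate(record_id: str, residues: str, kind: str) -> str:
    if kind == "protein":
        if "*" in residues:
            log.warning("stripping %d stop character(s) from record %r",
                        residues.count("*"), record_id)
            residues = residues.replace("*", "")
            if not residues:
                raise SequenceError(f"record {record_id!r} empty after stop stripping")
        alphabet = PROTEIN_ALPHABET
    elif kind == "nucleotide":
        alphabet = NUCLEOTIDE_ALPHABET
    else:
        raise ValueError(f"unknown sequence kind {kind!r}")
    for ch in residues:
        if ch not in alphabet:
            raise SequenceError(
                f"record {record_id!r} contains invalid {kind} character {ch!r}")
    return residues


def read_fasta(path: str | Path, kind: str = "protein") -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file into validated records.

    Headers are split at the first whitespace into id and description;
    multi-line sequences are joined and uppercased; order is preserved.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: tuple[str, str] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc = header
        residues = _validate(rid, "".join(chunks).upper(), kind)
        if rid in seen:
            raise SequenceError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        records.append(SequenceRecord(rid, residues, desc))

    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise SequenceError(f"empty FASTA header in {path}")
                header = (parts[0], parts[1] if len(parts) > 1 else "")
                chunks = []
            else:
                if header is None:
                    raise SequenceError(f"sequence data before first header in {path}")
                chunks.append(line.strip())
        flush()
    if not records:
        raise SequenceError(f"no records in {path}")
    return records


def read_proteome(path: str | Path, strain_id: str | None = None) -> Proteome:
    """Read one strain's proteome FASTA; strain id defaults to the file stem."""
    if strain_id is None:
        name = Path(path).name
        strain_id = re.sub(r"\.(faa|fa|fasta)(\.gz)?$", "", name)
    return Proteome(strain_id, read_fasta(path, kind="protein"))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with wrapped sequence lines (LF endings)."""
    records = list(records)
    if not records:
        raise SequenceError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("width must be positive")
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def write_aligned_fasta(rows: Iterable[tuple[str, str]], path: str | Path,
                        width: int = 60) -> None:
    """Write aligned rows (which may contain gap characters) as FASTA."""
    rows = list(rows)
    if not rows:
        raise SequenceError("refusing to write an empty FASTA file")
    with _open_text(path, "wt") as fh:
        for rid, row in rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read aligned FASTA into (id, row) pairs without alphabet validation
    beyond uppercase normalization (rows may contain gaps)."""
    rows: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    rows.append((header, "".join(chunks).upper()))
                header = line[1:].split(None, 1)[0]
                chunks = []
            else:
                chunks.append(line.strip())
        if header is not None:
            rows.append((header, "".join(chunks).upper()))
    if not rows:
        raise SequenceError(f"no records in {path}")
    return rows


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_string(tree: PhyloTree) -> str:
    """Serialize a tree: 6-decimal branch lengths, bootstrap support as
    integer-percent internal-node labels, trailing semicolon."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            if not node.name:
                raise TreeError("cannot serialize a tree with an unnamed leaf")
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(int(round(node.support)))
        return f"({inner}){label}:{node.length:.6f}"

    root = tree.root
    inner = ",".join(fmt(c) for c in root.children)
    label = "" if root.support is None else str(int(round(root.support)))
    return f"({inner}){label};"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(newick_string(tree) + "\n")


_TOKEN = re.compile(r"\s*([(),;:]|[^\s(),;:]+)")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (labels, branch lengths, internal support labels)."""
    tokens = _TOKEN.findall(text)
    if not tokens or tokens[-1] != ";":
        raise TreeError("Newick string must end with ';'")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_node() -> Node:
        node = Node()
        if peek() == "(":
            take()
            node.children.append(parse_node())
            while peek() == ",":
                take()
                node.children.append(parse_node())
            if take() != ")":
                raise TreeError("unbalanced parentheses in Newick string")
            if peek() not in ("(", ")", ",", ":", ";", None):
                label = take()
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            tok = peek()
            if tok in (")", ",", ":", ";", None):
                raise TreeError("missing leaf label in Newick string")
            node.name = take()
        if peek() == ":":
            take()
            node.length = float(take())
        return node

    root = parse_node()
    if take() != ";" or pos != len(tokens):
        raise TreeError("trailing content after Newick tree")
    return PhyloTree(root)


def read_newick(path: str | Path) -> PhyloTree:
    with _open_text(path) as fh:
        return parse_newick(fh.read())
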