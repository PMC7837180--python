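"""End-to-end orchestration: orthology → alignment → supermatrix → block
filter → distances → NJ → bootstrap, with all intermediates written out.

The run report mirrors the headline quantities of a core-proteome study:
number of proteomes, core ortholog groups, super-alignment length,
retained columns after filtering, variable sites, and the support-
annotated tree.  Runs are fully deterministic for a fixed seed; the
report deliberately excludes wall-clock information so that re-runs are
byte-identical (timings go to the log stream).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import blockfilter, msa, orthology, phylo, supermatrix
from .seqio import Proteome, read_proteome, write_aligned_fasta, write_newick

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT = 2
EXIT_EMPTY_CORE = 3
EXIT_INTERNAL = 4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = EXIT_INPUT):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    e_cutoff: float = 1e-5
    bootstrap_replicates: int = 500
    seed: int = 42
    gap_open: int = 11
    gap_extend: int = 1
    msa_gap_open: float = 10.0
    msa_gap_extend: float = 0.5
    kmer_size: int = 3


@dataclass
class RunReport:
    n_proteomes: int
    n_core_groups: int
    superalignment_length: int
    retained_columns: int
    variable_sites: int
    tree_path: str
    stage_notes: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.variable_sites <= self.retained_columns <= self.superalignment_length):
            raise PipelineError("report", "report arithmetic invariant violated",
                                EXIT_INTERNAL)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def load_proteomes(directory: str | Path) -> list[Proteome]:
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix in (".faa", ".fa", ".fasta")
                   or p.name.endswith((".faa.gz", ".fa.gz", ".fasta.gz")))
    if not paths:
        raise PipelineError("input", f"no proteome FASTA files in {directory}")
    return [read_proteome(p) for p in paths]


def run_pipeline(proteomes: Sequence[Proteome] | str | Path, reference: str,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> tuple[RunReport, phylo.PhyloTree]:
    """Run every stage in order and return (report, support-annotated tree).

    ``proteomes`` is either a directory of per-strain FASTA files or an
    in-memory list; ``reference`` names the anchor strain.  When
    ``outdir`` is given, all intermediates are written there
    (groups.tsv, aln_dir/, super.fasta, partitions.tsv, mask.json,
    dist.phy, tree.nwk, report.json).
    """
    config = config or PipelineConfig()
    if isinstance(proteomes, (str, Path)):
        proteomes = load_proteomes(proteomes)
    proteomes = list(proteomes)
    if len(proteomes) < 4:
        raise PipelineError("input", "need at least 4 proteomes")
    by_strain = {p.strain_id: p for p in proteomes}
    if reference not in by_strain:
        raise PipelineError("input", f"reference strain {reference!r} not found")
    ref = by_strain[reference]
    others = [p for p in proteomes if p.strain_id != reference]
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    scheme = orthology.ScoringScheme.blosum62(
        gap_open=config.gap_open, gap_extend=config.gap_extend)
    notes: dict[str, str] = {}

    t0 = time.monotonic()
    groups = orthology.extract_core_groups(ref, others, scheme, config.e_cutoff)
    log.info("orthology: %d core groups from %d reference proteins (%.1fs)",
             len(groups), len(ref), time.monotonic() - t0)
    notes["orthology"] = f"{len(ref)} reference proteins -> {len(groups)} core groups"
    if not groups:
        raise PipelineError("orthology", "no core proteome: zero ortholog groups "
                            "shared by all strains", EXIT_EMPTY_CORE)
    if out is not None:
        with open(out / "groups.tsv", "w") as fh:
            fh.write("group_id\tstrain_id\tprotein_id\n")
            for g in groups:
                for strain in sorted(g.members):
                    fh.write(f"{g.reference_protein_id}\t{strain}\t{g.members[strain]}\n")

    t0 = time.monotonic()
    params = msa.MsaParams(k=config.kmer_size, gap_open=config.msa_gap_open,
                           gap_extend=config.msa_gap_extend)
    strain_order = sorted(by_strain)
    aligned: list[tuple[str, msa.Alignment]] = []
    for g in groups:
        seqs = [(s, by_strain[s][g.members[s]].residues) for s in strain_order]
        aln = msa.progressive_align(seqs, scheme, params)
        aligned.append((g.reference_protein_id, aln))
    log.info("msa: aligned %d groups (%.1fs)", len(aligned), time.monotonic() - t0)
    notes["msa"] = f"{len(aligned)} group alignments"
    if out is not None:
        aln_dir = out / "aln_dir"
        aln_dir.mkdir(exist_ok=True)
        for gid, aln in aligned:
            write_aligned_fasta(aln.rows, aln_dir / f"{gid}.afa")

    sa = supermatrix.concatenate(aligned)
    notes["supermatrix"] = f"{len(sa.rows)} strains x {sa.length} columns"

    t0 = time.monotonic()
    fparams = blockfilter.BlockFilterParams.defaults(len(sa.rows))
    blocks = blockfilter.apply_filter(sa, fparams)
    retained = sa.retained_columns()
    if retained == 0:
        log.warning("block filter retained no columns")
    notes["blockfilter"] = f"{len(blocks)} blocks, {retained}/{sa.length} columns retained"
    log.info("blockfilter: %s (%.1fs)", notes["blockfilter"], time.monotonic() - t0)
    variable = supermatrix.count_variable_sites(sa, respect_mask=True)

    if out is not None:
        write_aligned_fasta(sa.rows, out / "super.fasta")
        with open(out / "partitions.tsv", "w") as fh:
            fh.write("group_id\tstart\tend\n")
            for gid, start, end in sa.partitions:
                fh.write(f"{gid}\t{start}\t{end}\n")
        with open(out / "mask.json", "w") as fh:
            json.dump({"retained": [[int(a), int(b)] for a, b in blocks]}, fh)
            fh.write("\n")

    t0 = time.monotonic()
    dm = phylo.distance_matrix(sa)
    tree = phylo.neighbor_joining(dm)
    tree = phylo.bootstrap_support(sa, tree, config.bootstrap_replicates, config.seed)
    log.info("phylo: NJ + %d bootstrap replicates (%.1fs)",
             config.bootstrap_replicates, time.monotonic() - t0)
    notes["phylo"] = (f"NJ over {len(dm.taxa)} taxa, "
                      f"{config.bootstrap_replicates} bootstrap replicates")

    # relative artifact name: keeps report.json independent of where it lives
    tree_path = "tree.nwk"
    if out is not None:
        with open(out / "dist.phy", "w") as fh:
            fh.write(dm.to_phylip())
        write_newick(tree, out / "tree.nwk")

    report = RunReport(
        n_proteomes=len(proteomes),
        n_core_groups=len(groups),
        superalignment_length=sa.length,
        retained_columns=retained,
        variable_sites=variable,
        tree_path=tree_path,
        stage_notes=notes,
        config={"e_cutoff": config.e_cutoff,
                "bootstrap_replicates": config.bootstrap_replicates,
                "seed": config.seed,
                "gap_open": config.gap_open,
                "gap_extend": config.gap_extend,
                "msa_gap_open": config.msa_gap_open,
                "msa_gap_extend": config.msa_gap_extend,
                "kmer_size": config.kmer_size},
    )
    if out is not None:
        with open(out / "report.json", "w") as fh:
            fh.write(report.to_json())
    return report, tree
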