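# phylocore

Core-proteome supermatrix phylogenomics for bacterial strains, built as a
small, fully tested Python library with a thin `phylocore` command-line
wrapper.

Placing a newly sequenced strain inside a species complex (for example a
*Bacillus subtilis* biocontrol isolate among dozens of *sensu lato*
relatives) is classically done from whole proteomes rather than single
marker genes: pick the new strain as reference, call single-copy
orthologs in every other strain by reciprocal best hits, keep the
proteins present in *all* strains (the core proteome), align each
ortholog group, concatenate the alignments into one super-alignment,
strip poorly aligned columns, and infer a distance tree with bootstrap
support. `phylocore` implements that whole chain, plus the genome
composition summaries (GC content, windowed GC skew) that accompany a
genome announcement, and a calibrated proteome-evolution simulator so
the pipeline can be verified end to end against a known tree without
downloading anything.

## The method

For a reference proteome R and strains S₁…Sₙ:

1. **Orthology** — for each protein r ∈ R and each strain S, find the
   highest-scoring local alignment (exact Smith–Waterman, BLOSUM62,
   affine gaps: a gap of length k costs 11 + k) with Karlin–Altschul
   expectation E = K·m·n·e^(−λ·score) ≤ 10⁻⁵; a pair (r, s) is orthologous
   when each is the other's best hit, and r is *core* when it has such a
   partner in every strain.
2. **Alignment** — each core group is aligned progressively: k-mer
   dissimilarities → UPGMA guide tree → profile–profile global alignment
   with sum-of-pairs BLOSUM62 column scores.
3. **Supermatrix** — per-group alignments are concatenated column-wise
   with partition bookkeeping; variable sites are columns with ≥ 2
   distinct non-gap, non-X residues.
4. **Block filtering** — Gblocks-style column classification
   (nonconserved / conserved / highly conserved, thresholds
   IS = ⌊N/2⌋+1 and FS = ⌈0.85·N⌉ for N sequences) followed by the four
   selection rules: drop gap columns and adjacent nonconserved runs, drop
   nonconserved stretches longer than 8 columns, trim segments to
   highly-conserved flanks, drop blocks shorter than 10 columns.
5. **Tree** — pairwise observed difference proportions p (pairwise
   deletion over retained columns) are corrected for multiple hits with
   the Kimura protein formula d = −ln(1 − p − 0.2p²), trees are built by
   Saitou–Nei neighbor joining (Studier–Keppler Q criterion), and each
   internal edge gets bootstrap support from column-resampling
   replicates. Trees serialize to Newick with support as internal node
   labels, ready for iTOL-style viewers.

The simulator evolves core genes down a random tree under the uniform
20-state Markov model, where a branch of length b changes each site with
probability (19/20)(1 − e^(−(20/19)b)) — a closed form that makes the
generator's divergence exactly checkable — and salts each strain with
random decoy genes that reciprocal-best-hit calling must reject.

## Worked example

`python examples/01_full_pipeline_on_simulated_strains.py` simulates 12
strains (20 core genes × 200 aa, 5 decoys per strain, expected
root-to-tip divergence 0.3 substitutions/site) and runs the pipeline:

```
proteomes:              12
core ortholog groups:   20   (simulated: 20)
super-alignment length: 4000 columns
retained after filter:  4000 columns
variable sites:         3062
RF distance to truth:   0
bootstrap support:      min 97%, max 100%
```

All 20 simulated core genes — and none of the 60 decoys — were
recovered as ortholog groups; the inferred tree matches the generating
tree exactly (Robinson–Foulds distance 0) and every internal edge is
supported by ≥ 97 of 100 bootstrap replicates. The other example scripts
demonstrate GC-skew profiling, reciprocal-best-hit calling, conserved-
block filtering, and distance/NJ inference in isolation.

The same run is available from a shell:

```sh
phylocore simulate --taxa 12 --genes 20 --len 200 --decoys 5 --seed 4 --out simdir/
phylocore run --proteomes simdir/ --ref S01 --bootstrap 100 --seed 4 --out outdir/
```

writing `groups.tsv`, per-group alignments, `super.fasta`,
`partitions.tsv`, `mask.json`, `dist.phy`, `tree.nwk` and `report.json`.

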