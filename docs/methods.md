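# Methods

This note records the models, defaults and design choices behind
`phylocore`, in the order the pipeline runs them, together with the
numerical conventions and known limitations.

## Orthology: exact local alignment instead of heuristic search

Ortholog calling is reference-anchored reciprocal best hit (RBH): r in
the reference and s in another strain are partners iff s is r's
top-scoring hit and r is s's. At the scale this package targets
(dozens of strains, simulated or curated proteomes) there is no need for
heuristic seeded search: scores are **exact Smith–Waterman** local
alignments under affine gaps, with the classic protein-search defaults —
BLOSUM62 (taken from Biopython's matrix collection), gap open 11, gap
extend 1, a gap of length k costing `open + k·extend`. Exact DP makes
hits a strict superset of what a seeded heuristic would find, so RBH
calls can only be more complete. The inner loops are numba-compiled;
scoring is symmetric, so one all-pairs score table serves both search
directions of an RBH computation.

Significance uses the Karlin–Altschul expectation E = K·m·n·e^(−λS)
with the standard gapped-BLOSUM62 constants λ = 0.267 nats and
K = 0.041, no finite-size correction. The cutoff (default 10⁻⁵) acts as
a permissive filter ahead of the much stricter "present in all strains"
requirement, so the exact constants matter little; both are
configurable, and a substitution matrix can be loaded from NCBI matrix
text. Ties in best-hit selection break by higher score, then
lexicographically smaller subject id, making the whole stage
deterministic. `X` is scored by the matrix's own X row (−1 against
everything), keeping scoring total over the alphabet.

## Progressive alignment

The per-group aligner is a deliberate first-iteration MUSCLE analogue:
k-mer dissimilarity 1 − |shared k-mers| / min(|kmers(a)|, |kmers(b)|)
(k = 3, reduced automatically if a sequence is shorter), a UPGMA guide
tree with ties broken toward the lexicographically smallest cluster-label
pair, and profile–profile global alignment along the tree. Column scores
are sum-of-pairs expected BLOSUM62 scores (gap symbols contribute zero);
new gaps cost open 10 / extend 0.5 per sequence pair spanned, and
terminal gaps are penalized like internal ones. For two sequences this
reduces exactly to pairwise global affine-gap alignment, which the tests
exploit as an oracle. Iterative refinement and anchoring are
intentionally out of scope: downstream signal comes from thousands of
concatenated columns, not from perfecting individual columns. Row order
always equals input order and de-gapping any row must reproduce its
input exactly; the aligner verifies this invariant on every call.

## Supermatrix and variable sites

Concatenation requires an identical strain set in every group — a
missing strain is an error naming group and strain, never silently
gap-padded, because core-group construction guarantees full occupancy
and a violation indicates a bug upstream. A *variable site* is a column
with at least two distinct non-gap, non-X residues; excluding gaps and
ambiguity makes the count invariant to gap coding. The definition
matters when comparing counts across tools, since published totals
depend on it.

## Conserved-block filtering

Column classification for N sequences uses the published default
arithmetic, pinned explicitly including rounding direction:
IS = ⌊N/2⌋+1 (minimum agreement for "conserved"), FS = ⌈0.85·N⌉
("highly conserved"), maximum nonconserved stretch CP = 8, minimum block
length BL = 10, and no gaps allowed (any gap makes a gap column; a
"half" mode tolerating gaps in up to half the rows exists as a stub).
The most frequent residue is counted by exact character identity; X
counts as its own residue. Selection applies four rules in a fixed
order: (1) remove gap columns and every nonconserved run adjacent to
one; (2) remove nonconserved runs longer than CP; (3) trim each
surviving segment back to its outermost highly-conserved columns;
(4) drop segments shorter than BL. Empty retention is legal and
reported, not an error. The filter runs on the concatenated
super-alignment, not per gene.

## Distances, neighbor joining, bootstrap

Observed difference proportions use pairwise deletion: only columns
where both rows carry an unambiguous residue (and the retention mask
keeps the column) are compared; a pair with zero comparable sites is an
error naming the pair. Multiple hits are corrected with the Kimura
(1983) protein formula d = −ln(1 − p − 0.2p²), the correction protein-NJ
front ends traditionally apply. Its domain ends near p ≈ 0.854;
saturated pairs are capped at a configurable d = 10 with a warning
rather than resorting to table lookup — simple, monotone, and explicit
in logs.

Neighbor joining is the Saitou–Nei agglomeration with the
Studier–Keppler criterion Q(i,j) = (m−2)·d(i,j) − r(i) − r(j). Ties in Q
break toward the lexicographically smallest pair of cluster labels
(each cluster labelled by its smallest leaf), so output is deterministic
for any input order. Negative limb-length estimates are clamped to zero;
this affects lengths only, never the join order. On an additive matrix
the algorithm is exact: the returned tree reproduces the input metric to
1e-9, which the test suite asserts on hundreds of random trees.

Bootstrap support resamples the retained columns with replacement (same
count), recomputes distances and an NJ tree per replicate, and maps
bipartition frequencies onto the internal edges of the full-data tree —
one tree annotated with support, no consensus construction. A single
seeded PCG64 generator drives all replicates in sequence, so one seed
fixes every support value; the pipeline report is written without
timestamps or absolute paths so that re-runs with the same seed are
byte-identical.

## Simulator

The generator exists to make every stage falsifiable against ground
truth. Topologies come from random sequential addition (unrooted binary;
2n−3 branches); branch lengths are Exp(1) draws rescaled so the mean
root-to-tip path equals `tree_depth` (default 0.3 substitutions/site).
Core genes start as uniform-random sequences at the (trifurcating) root
and evolve down each branch under the **uniform 20-state Markov model**:
along a branch of length b each site changes with probability
(19/20)(1 − e^(−(20/19)b)), to a uniformly drawn different residue. This
model was chosen over a BLOSUM-weighted chain precisely because its
pairwise divergence has a closed form, giving the module a sharp
calibration contract (observed differences must sit inside the binomial
interval of the expectation). Under this model the Kimura protein
correction is a biased estimator of path length; it remains monotone in
p, so topology — the surface the pipeline is judged on — is generally
preserved, but short internal edges can be distorted (see Limitations).
Decoy genes are fresh random sequences per strain drawn from the same
residue distribution as the roots, making RBH rejection non-trivial, and
protein ids are shuffled per strain so file order carries no orthology
signal. There is no indel process by default (simulated orthologs stay
length-aligned, so the alignment stage is exercised but trivially
correct); an optional indel rate with geometric deletion lengths exists
for stress-testing the aligner's lossless-row invariant.

Default conditions used by the end-to-end tests and the acceptance
script: 12 taxa, 20 core genes × 200 residues, 5 decoys per strain,
depth 0.3, 100 bootstrap replicates. These sizes keep a full five-seed
acceptance run in the tens of seconds while leaving ~4,000 supermatrix
columns — enough signal that edges of typical length are recovered with
high support.

## Genome composition

GC content is (G+C)/(A+C+G+T) with ambiguous bases excluded from both
numerator and denominator; a sequence with no unambiguous base is an
error. GC skew is (G−C)/(G+C) per non-overlapping window (default
10 kb); a window with no G or C records NaN and does not advance the
cumulative sum. The chromosome is treated as linear even when
biologically circular — no wraparound window — which only blurs the
single window spanning the origin of the coordinate system.

## Numerical and formatting conventions

Newick output writes branch lengths to 6 decimals and bootstrap support
as integer-percent internal-node labels; round-trips preserve leaf sets,
bipartitions and lengths to 1e-6. FASTA round-trips are the identity on
(id, description, residues); CRLF input is accepted, LF written; `*`
stop characters are stripped from proteins with a logged warning.
Distance matrices export in square PHYLIP form. All randomness flows
through explicitly seeded PCG64 generators.

## Test-size choices

The local-alignment oracle checks run exhaustively over all sequence
pairs of lengths ≤ 2 on a four-residue sub-alphabet and on a
2,000-pair seeded random sample of lengths ≤ 6, against an independent
Waterman–Smith–Beyer general-gap DP; a smaller sample is additionally
checked against a full enumeration of alignment move sequences. Complete
enumeration of all ≤-6-length pairs (~15M ordered pairs) adds no
coverage class beyond these and is omitted. NJ exactness uses 200 random
trees of 4–15 taxa; block-filter invariants use 1,000 randomized status
strings.

## Limitations

- The simulator omits site-rate heterogeneity, indels (by default),
  horizontal transfer, gene gain/loss and paralogy beyond simple decoys;
  passing tests demonstrate pipeline correctness under clean vertical
  descent, not robustness to real pan-genome dynamics.
- The Kimura protein correction is model-mismatched for the uniform
  20-state generator (and for real proteins, differently). At the
  default study scale this can leave very short internal edges
  unresolved or weakly supported: an edge of ~2·10⁻⁴ substitutions/site
  carries less than one expected substitution across 4,000 columns and
  is unrecoverable by any method, and exponential branch-length draws
  make one such edge among ~9 internal edges fairly common. Perfect
  topology recovery across replicate simulations should therefore not be
  expected, and branch *lengths* are estimated under the wrong model by
  design.
- E-values use fixed Karlin–Altschul constants with no edge correction;
  they are a filter, not calibrated significance.
- The aligner is order-deterministic but, like all progressive methods,
  its columns for ≥ 3 sequences can depend on input order through guide
  tree ties; only determinism under fixed input order is guaranteed.
- The block filter's "half" gap mode and codon-aware filtering are not
  implemented.
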