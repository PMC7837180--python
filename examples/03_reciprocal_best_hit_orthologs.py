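"""Call orthologs between two toy proteomes by reciprocal best hits.

Each proteome holds two genuine orthologs (slightly diverged copies) and
one unrelated decoy; exact Smith-Waterman scores plus a Karlin-Altschul
E-value cutoff recover exactly the true pairs.
"""

from phylocore import reciprocal_best_hits, smith_waterman_score
from phylocore.seqio import Proteome, SequenceRecord

ref = Proteome("strainA", [
    SequenceRecord("a1", "MKVLWAALKKEEFFDD"),
    SequenceRecord("a2", "GGSSHHEEPPQQRRYY"),
    SequenceRecord("a_decoy", "CCCCCCCCCCCCCCCC"),
])
other = Proteome("strainB", [
    SequenceRecord("b1", "MKVLWAALKKEEYFDD"),   # a1 with one substitution
    SequenceRecord("b2", "GGSSHHEEPPQQRRYW"),   # a2 with one substitution
    SequenceRecord("b_decoy", "NNDDNNDDNNDDNNDD"),
])

print("pairwise local-alignment scores (BLOSUM62, open 11 / extend 1):")
for r in ref.records:
    row = "  ".join(f"{s.id}:{smith_waterman_score(r.residues, s.residues):>3}"
                    for s in other.records)
    print(f"  {r.id:<8} {row}")

mapping = reciprocal_best_hits(ref, other, e_cutoff=1e-2)
print(f"\nreciprocal best hits: {mapping}")
# Only a1<->b1 and a2<->b2 are mutual best hits below the E-value cutoff;
# the decoys score too low in every direction and drop out.
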