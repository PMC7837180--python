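"""Kimura-corrected distances and neighbor joining on a tiny alignment.

Four aligned rows give observed difference proportions (pairwise
deletion), the Kimura protein correction inflates them for multiple
hits, and NJ resolves the quartet.
"""

from phylocore import (DistanceMatrix, distance_matrix, kimura_correct,
                       neighbor_joining, p_distance)
from phylocore.msa import Alignment
from phylocore.supermatrix import concatenate

rows = [("S1", "MKVLWAALKKEEMKVLWAALKKEE"),
        ("S2", "MKVLWAALKKEDMKVLWAALKKED"),
        ("S3", "MKVIWGALKQEEMKVIWGALKQEE"),
        ("S4", "MKVIWGALQQEEMKVIWGALQQEE")]
sa = concatenate([("demo", Alignment(rows))])

p = p_distance(rows[0][1], rows[2][1])
print(f"observed p(S1,S3)      = {p:.4f}")
print(f"Kimura-corrected d     = {kimura_correct(p):.4f}")

dm = distance_matrix(sa)
tree = neighbor_joining(dm)
print("\ndistance matrix (substitutions/site):")
print(dm.to_phylip())
print("NJ tree:", tree.to_newick())
# S1/S2 and S3/S4 differ by one site each but share blocks of substitutions,
# so NJ pairs them: the Newick shows the (S1,S2)|(S3,S4) split.
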