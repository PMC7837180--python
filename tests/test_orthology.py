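import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import sw_enum, sw_wsb
from phylocore import orthology as orth
from phylocore.seqio import Proteome, SequenceRecord
from phylocore.simulate import SimConfig

seqs4 = st.text(alphabet="ACDE", min_size=1, max_size=5)


class TestSmithWaterman:
    @pytest.mark.parametrize("a,b,expected", [
        ("MKV", "MKV", 14),    # 5 + 5 + 4 on the BLOSUM62 diagonal
        ("AAAA", "WWWW", 0),   # no positive-scoring local alignment
        ("MKVW", "MKW", 11),   # lone W-W (11) beats MK (10)
    ])
    def test_hand_checked_scores(self, a, b, expected):
        assert orth.smith_waterman_score(a, b) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            orth.smith_waterman_score("", "MKV")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seqs4, seqs4)
    def test_matches_general_gap_oracle(self, scheme, a, b):
        S = scheme.matrix.astype(float)
        assert orth.smith_waterman_score(a, b, scheme) == pytest.approx(
            sw_wsb(a, b, S, scheme.gap_open, scheme.gap_extend))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDE", min_size=1, max_size=3),
           st.text(alphabet="ACDE", min_size=1, max_size=3))
    def test_matches_move_enumeration_oracle(self, scheme, a, b):
        S = scheme.matrix.astype(float)
        assert orth.smith_waterman_score(a, b, scheme) == pytest.approx(
            max(0.0, sw_enum(a, b, S, scheme.gap_open, scheme.gap_extend)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seqs4, seqs4)
    def test_symmetry(self, a, b):
        assert orth.smith_waterman_score(a, b) == orth.smith_waterman_score(b, a)


class TestEvalue:
    def test_zero_score(self):
        assert orth.evalue(0, 100, 100) == pytest.approx(410.0)

    def test_formula_at_score_40(self):
        assert orth.evalue(40, 100, 100) == pytest.approx(
            0.041 * 1e4 * math.exp(-0.267 * 40))
        assert orth.evalue(40, 100, 100) == pytest.approx(9.43e-3, rel=1e-3)

    def test_strictly_decreasing_in_score(self):
        values = [orth.evalue(s, 100, 100) for s in range(0, 120, 7)]
        assert all(x > y for x, y in zip(values, values[1:]))


def proteome(strain, *seqs):
    return Proteome(strain, [SequenceRecord(f"{strain}_p{i}", s)
                             for i, s in enumerate(seqs, 1)])


class TestBestHit:
    def test_identity_hit(self):
        target = proteome("T", "MKVLWAAL", "GGSSGG")
        q = SequenceRecord("q", "MKVLWAAL")
        hit = orth.best_hit(q, target, e_cutoff=1.0)
        assert hit.subject_id == "T_p1"

    def test_all_above_cutoff_gives_none(self):
        target = proteome("T", "GG")
        q = SequenceRecord("q", "MM")
        assert orth.best_hit(q, target, e_cutoff=1e-30) is None

    def test_tie_broken_lexicographically(self):
        target = proteome("T", "MKVLW", "MKVLW")  # equal scores
        q = SequenceRecord("q", "MKVLW")
        assert orth.best_hit(q, target, e_cutoff=1.0).subject_id == "T_p1"


class TestReciprocalBestHits:
    def test_self_rbh_is_identity(self):
        p = proteome("A", "MKVLWAALKK", "GGSSGGHHEE", "WWYYFFMMCC")
        q = Proteome("B", [SequenceRecord(r.id.replace("A", "B"), r.residues)
                           for r in p.records])
        m = orth.reciprocal_best_hits(p, q, e_cutoff=10.0)
        assert m == {"A_p1": "B_p1", "A_p2": "B_p2", "A_p3": "B_p3"}

    def test_non_reciprocal_pair_excluded(self):
        # r1's best hit in B is b1, but b1's best hit in A is r2
        ref = proteome("A", "MKVLWAAL", "MKVLWAALKKEE")
        other = proteome("B", "MKVLWAALKKEE")
        m = orth.reciprocal_best_hits(ref, other, e_cutoff=10.0)
        assert "A_p1" not in m
        assert m.get("A_p2") == "B_p1"

    def test_injective_both_directions(self, small_simulation):
        _, proteomes, _ = small_simulation
        m = orth.reciprocal_best_hits(proteomes[0], proteomes[1])
        assert len(set(m.values())) == len(m)

    def test_toy_orthologs_with_decoy(self, rng):
        """Two 3-protein proteomes with two diverged ortholog pairs and one
        decoy each: brute-force all-pairs scoring finds exactly the 2 pairs."""
        a1, a2 = "MKVLWAALKKEEFF", "GGSSHHEEPPQQRR"
        b1 = "MKVLWAALKKEEYF"   # a1 with one substitution
        b2 = "GGSSHHEEPPQQRW"   # a2 with one substitution
        ref = Proteome("A", [SequenceRecord("a1", a1), SequenceRecord("a2", a2),
                             SequenceRecord("ax", "CCCCCCCCCCCCCC")])
        oth = Proteome("B", [SequenceRecord("b2", b2), SequenceRecord("b1", b1),
                             SequenceRecord("bx", "NNDDNNDDNNDDNN")])
        m = orth.reciprocal_best_hits(ref, oth, e_cutoff=1e-2)
        assert m == {"a1": "b1", "a2": "b2"}


class TestExtractCoreGroups:
    def test_missing_partner_drops_group(self):
        ref = proteome("R", "MKVLWAALKKEE", "GGSSHHEEPPQQ", "WWYYFFMMCCHH")
        o1 = proteome("S1", "MKVLWAALKKEE", "GGSSHHEEPPQQ", "WWYYFFMMCCHH")
        o2 = proteome("S2", "MKVLWAALKKEE", "WWYYFFMMCCHH")  # lacks p2's partner
        groups = orth.extract_core_groups(ref, [o1, o2], e_cutoff=1e-2)
        assert [g.reference_protein_id for g in groups] == ["R_p1", "R_p3"]

    def test_copy_of_ref_keeps_every_protein(self):
        ref = proteome("R", "MKVLWAALKKEE", "GGSSHHEEPPQQ")
        copy = Proteome("C", [SequenceRecord(r.id.replace("R", "C"), r.residues)
                              for r in ref.records])
        groups = orth.extract_core_groups(ref, [copy], e_cutoff=1e-2)
        assert len(groups) == len(ref)

    def test_simulated_ground_truth_recovered(self, small_simulation):
        """On simulated strains the extracted groups are exactly the true
        ortholog map; decoys never enter any group."""
        cfg, proteomes, truth = small_simulation
        ref = proteomes[0]
        others = proteomes[1:]
        groups = orth.extract_core_groups(ref, others)
        assert len(groups) == cfg.n_core_genes
        by_ref = {g.reference_protein_id: g for g in groups}
        for gene, members in truth.ortholog_map.items():
            g = by_ref[members[ref.strain_id]]
            assert g.members == members
        decoy_ids = {pid for ids in truth.decoys.values() for pid in ids}
        for g in groups:
            assert not decoy_ids & set(g.members.values())

    def test_cutoff_monotonicity(self, small_simulation):
        _, proteomes, _ = small_simulation
        ref, others = proteomes[0], proteomes[1:3]
        loose = {g.reference_protein_id
                 for g in orth.extract_core_groups(ref, others, e_cutoff=1e-3)}
        tight = {g.reference_protein_id
                 for g in orth.extract_core_groups(ref, others, e_cutoff=1e-12)}
        assert tight <= loose


class TestScoringScheme:
    def test_matrix_must_be_symmetric(self):
        m = orth.load_matrix()
        m = m.copy()
        m[0, 1] += 1
        with pytest.raises(ValueError):
            orth.ScoringScheme(matrix=m)

    def test_ncbi_matrix_text_round_trip(self, scheme):
        alpha = orth.ALPHABET
        header = "   " + "  ".join(alpha)
        lines = [header]
        for i, a in enumerate(alpha):
            lines.append(a + " " + " ".join(str(int(v)) for v in scheme.matrix[i]))
        parsed = orth.parse_matrix_text("# comment\n" + "\n".join(lines))
        assert np.array_equal(parsed, scheme.matrix)

    def test_x_scores_are_total(self, scheme):
        assert orth.smith_waterman_score("MXM", "MXM", scheme) >= 0
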