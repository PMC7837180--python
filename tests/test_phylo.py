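import math

import numpy as np
import pytest

from oracles import pairwise_p_count
from phylocore import phylo
from phylocore.msa import Alignment
from phylocore.seqio import parse_newick
from phylocore.supermatrix import concatenate
from phylocore.tree import Node, PhyloTree, TreeError, robinson_foulds
from phylocore.simulate import sample_tree


class TestPDistance:
    def test_identical_rows(self):
        assert phylo.p_distance("MKVLW", "MKVLW") == 0.0

    def test_quarter_difference(self):
        assert phylo.p_distance("MMMM", "MMMK") == 0.25

    def test_pairwise_deletion_of_gap_columns(self):
        assert phylo.p_distance("M-MM", "MKMA") == pytest.approx(1 / 3)

    def test_x_columns_excluded(self):
        assert phylo.p_distance("MXMM", "MKMM") == 0.0

    def test_mask_restricts_columns(self):
        mask = np.array([True, False, True, True])
        assert phylo.p_distance("MKMM", "MAMK", mask) == pytest.approx(1 / 3)

    def test_zero_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            phylo.p_distance("M-", "-M")

    def test_matches_direct_count_on_random_rows(self, rng):
        chars = np.array(list("MKVLW-X"))
        for _ in range(25):
            a = "".join(rng.choice(chars, size=40))
            b = "".join(rng.choice(chars, size=40))
            diff, comp = pairwise_p_count(a, b)
            if comp == 0:
                continue
            assert phylo.p_distance(a, b) == pytest.approx(diff / comp)


class TestKimuraCorrection:
    def test_zero(self):
        assert phylo.kimura_correct(0.0) == 0.0

    def test_reference_value(self):
        # -ln(1 - 0.2 - 0.2*0.04) = -ln(0.792)
        assert phylo.kimura_correct(0.2) == pytest.approx(-math.log(0.792))
        assert phylo.kimura_correct(0.2) == pytest.approx(0.23319, abs=1e-5)

    def test_saturation_capped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert phylo.kimura_correct(0.86) == phylo.DISTANCE_CAP
        assert "capped" in caplog.text

    def test_strictly_increasing_and_at_least_p(self):
        ps = np.linspace(0.0, 0.85, 200)
        ds = phylo.kimura_correct(ps)
        assert np.all(np.diff(ds) > 0)
        assert np.all(ds >= ps)

    def test_domain_validated(self):
        with pytest.raises(ValueError):
            phylo.kimura_correct(1.5)


def make_sa(rows):
    return concatenate([("g", Alignment(rows))])


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        sa = make_sa([("a", "MKVLW"), ("b", "MKVLW"), ("c", "MKVLW")])
        dm = phylo.distance_matrix(sa)
        assert np.all(dm.values == 0)

    def test_hand_counted_three_strains(self):
        sa = make_sa([("a", "MMMM"), ("b", "MMMK"), ("c", "MMKK")])
        dm = phylo.distance_matrix(sa)
        expect = {("a", "b"): 0.25, ("a", "c"): 0.5, ("b", "c"): 0.25}
        for (x, y), p in expect.items():
            i, j = dm.taxa.index(x), dm.taxa.index(y)
            assert dm.values[i, j] == pytest.approx(phylo.kimura_correct(p))

    def test_symmetry_and_zero_diagonal_validated(self):
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], np.array([[0, np.inf], [np.inf, 0]]))

    def test_phylip_export_shape(self):
        sa = make_sa([("a", "MMMM"), ("b", "MMMK"), ("c", "MMKK")])
        text = phylo.distance_matrix(sa).to_phylip()
        lines = text.strip().splitlines()
        assert lines[0].strip() == "3" and len(lines) == 4


def star3(da, db, dc):
    return PhyloTree(Node(children=[Node("A", da), Node("B", db), Node("C", dc)]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        t = phylo.neighbor_joining(phylo.DistanceMatrix(["A", "B", "C"], d))
        lengths = {n.name: n.length for n in t.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_matrix(self):
        # additive distances of the tree ((A:1,B:2):1,(C:3,D:4))
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0.0]])
        t = phylo.neighbor_joining(phylo.DistanceMatrix(taxa, d))
        assert t.bipartitions() == {frozenset("CD")}
        names, mat = t.path_length_matrix()
        assert names == taxa
        assert np.allclose(np.array(mat), d, atol=1e-9)

    def test_additive_consistency_random_trees(self):
        """NJ run on a tree's exact path-length metric returns that tree."""
        for seed in range(20):
            n = 4 + seed % 9
            true = sample_tree(n, tree_depth=0.5, seed=seed)
            names, mat = true.path_length_matrix()
            t = phylo.neighbor_joining(phylo.DistanceMatrix(names, np.array(mat)))
            assert robinson_foulds(t, true) == 0
            _, mat2 = t.path_length_matrix()
            assert np.allclose(np.array(mat2), np.array(mat), atol=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        for _ in range(5):
            n = 6
            true = sample_tree(n, tree_depth=0.5, seed=int(rng.integers(1 << 30)))
            names, mat = true.path_length_matrix()
            m = np.array(mat)
            m = (m + m.T) / 2  # exact symmetry for skbio's validator
            ours = phylo.neighbor_joining(phylo.DistanceMatrix(names, m))
            theirs = parse_newick(str(sk_nj(SkDM(m, ids=names))).strip())
            assert robinson_foulds(ours, theirs) == 0

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = phylo.DistanceMatrix(["D", "C", "B", "A"], d)
        t1 = phylo.neighbor_joining(dm).to_newick()
        t2 = phylo.neighbor_joining(dm).to_newick()
        assert t1 == t2

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(phylo.DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = sample_tree(8, 0.3, seed=5)
        assert robinson_foulds(t, t) == 0

    def test_distinct_quartet_resolutions(self):
        t1 = parse_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = parse_newick("((A:1,C:1):1,B:1,D:1);")
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_order_invariance(self):
        t1 = parse_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = parse_newick("(D:1,C:1,(B:1,A:1):1);")
        assert robinson_foulds(t1, t2) == 0

    def test_mismatched_leaf_sets_rejected(self):
        t1 = parse_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = parse_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(TreeError):
            robinson_foulds(t1, t2)

    def test_matches_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare
        for _ in range(5):
            a = sample_tree(7, 0.4, seed=int(rng.integers(1 << 30)))
            b = sample_tree(7, 0.4, seed=int(rng.integers(1 << 30)))
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            assert robinson_foulds(a, b) == treecompare.symmetric_difference(da, db)


class TestBootstrap:
    def four_taxon_sa(self):
        rows = [("A", "M" * 30 + "K" * 30), ("B", "M" * 30 + "K" * 30),
                ("C", "K" * 30 + "M" * 30), ("D", "K" * 30 + "M" * 30)]
        return make_sa(rows)

    def test_unanimous_split_gets_full_support(self):
        sa = self.four_taxon_sa()
        dm = phylo.distance_matrix(sa)
        ref = phylo.neighbor_joining(dm)
        t = phylo.bootstrap_support(sa, ref, replicates=25, seed=99)
        assert t.bipartition_support() == {frozenset("CD"): 100.0}

    def test_single_replicate_gives_zero_or_hundred(self):
        sa = self.four_taxon_sa()
        ref = phylo.neighbor_joining(phylo.distance_matrix(sa))
        t = phylo.bootstrap_support(sa, ref, replicates=1, seed=5)
        assert set(t.bipartition_support().values()) <= {0.0, 100.0}

    def test_seed_fixes_every_support_value(self, small_simulation):
        from phylocore import run_pipeline, PipelineConfig
        _, proteomes, _ = small_simulation
        ref = sorted(p.strain_id for p in proteomes)[0]
        cfg = PipelineConfig(bootstrap_replicates=20, seed=7)
        _, t1 = phylo_run(proteomes, ref, cfg)
        _, t2 = phylo_run(proteomes, ref, cfg)
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_four_taxa_rejected(self):
        sa = make_sa([("a", "MKV"), ("b", "MKV"), ("c", "MKV")])
        ref = phylo.neighbor_joining(phylo.distance_matrix(sa))
        with pytest.raises(ValueError):
            phylo.bootstrap_support(sa, ref, replicates=5, seed=1)

    def test_supports_within_range(self, small_simulation):
        _, proteomes, _ = small_simulation
        ref = sorted(p.strain_id for p in proteomes)[0]
        from phylocore import PipelineConfig
        _, tree = phylo_run(proteomes, ref, PipelineConfig(bootstrap_replicates=10, seed=3))
        for v in tree.bipartition_support().values():
            assert v is None or 0.0 <= v <= 100.0


def phylo_run(proteomes, ref, cfg):
    from phylocore import run_pipeline
    return run_pipeline(proteomes, ref, cfg)
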