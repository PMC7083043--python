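"""Distances, NJ exactness, bootstrap, rooting and tree congruence."""

import numpy as np
import pytest

from snpdiag.errors import DataError, RootingError, UsageError
from snpdiag.panel import GenotypeMatrix, SpeciesPanel
from snpdiag.phylo import (DistanceMatrix, bootstrap_support, collapse_to_species,
                           compare_trees, diversity_summary, nj_tree,
                           pairwise_differences, root_at_outgroup,
                           tree_bipartitions)
from snpdiag.simulate import parse_tree

from oracles import (newick_bipartitions_oracle, pairwise_oracle,
                     random_additive_matrix)

BASES = "ACGT"


def matrix_from_rows(rows, accs):
    alleles = np.array(rows, dtype=np.uint8).T
    sites = [("chr1", i + 1, "A") for i in range(alleles.shape[0])]
    return GenotypeMatrix(sites, alleles, accs)


class TestPairwiseDifferences:
    def test_identical_and_simple_counts(self):
        m = matrix_from_rows([[0, 1, 2, 3], [0, 1, 1, 1]], ["i", "j"])
        d = pairwise_differences(m)
        assert d.values[0, 0] == 0
        assert d.values[0, 1] == 2  # sites 3 and 4 differ

    def test_full_matrix_equals_double_loop_oracle(self, rng):
        accs = [f"a{i}" for i in range(7)]
        alleles = rng.integers(0, 4, size=(200, 7), dtype=np.uint8)
        m = GenotypeMatrix([("chr1", i + 1, "A") for i in range(200)], alleles, accs)
        by_acc = {a: [BASES[c] for c in m.column(a)] for a in accs}
        assert np.array_equal(pairwise_differences(m).values,
                              pairwise_oracle(by_acc, accs))

    def test_hamming_distance_is_a_metric(self, rng):
        accs = [f"a{i}" for i in range(6)]
        alleles = rng.integers(0, 4, size=(100, 6), dtype=np.uint8)
        m = GenotypeMatrix([("chr1", i + 1, "A") for i in range(100)], alleles, accs)
        d = pairwise_differences(m).values
        assert (d >= 0).all() and np.array_equal(d, d.T)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j]


class TestDiversitySummary:
    def test_median_and_gap_flag_on_stated_values(self):
        """Pairwise sets {10,12,300,310} -> median 156 with a dominant gap."""
        accs = ["s1", "s2", "s3", "s4"]
        panel = SpeciesPanel(accs, {a: "sp" for a in accs})
        d = np.zeros((4, 4))
        vals = {(0, 1): 10, (0, 2): 12, (0, 3): 300, (1, 2): 310, (1, 3): 300, (2, 3): 310}
        for (i, j), v in vals.items():
            d[i, j] = d[j, i] = v
        summaries = diversity_summary(DistanceMatrix(accs, d), panel)
        s = summaries[0]
        assert np.median([10, 12, 300, 310]) == 156.0
        assert s.multimodal

    def test_zero_terminal_branch_gives_all_zero_diversity(self, two_species_config):
        from snpdiag.calling import call_accession
        from snpdiag.panel import build_matrix
        from snpdiag.simulate import emit_pileups, evolve_panel, simulate_reference

        cfg = two_species_config  # species B has terminal branch 0
        truth = evolve_panel(simulate_reference(cfg), cfg)
        pileups = emit_pileups(truth, cfg)
        panel = cfg.panel()
        statuses = {a: call_accession(pileups[a], a)[1] for a in panel.accessions}
        m = build_matrix(statuses, panel)
        summaries = diversity_summary(pairwise_differences(m), panel)
        by_sp = {s.species: s for s in summaries}
        assert by_sp["B"].median == 0 and by_sp["B"].max == 0
        assert by_sp["A"].median > 0

    def test_singleton_species_skipped_with_warning(self):
        panel = SpeciesPanel(["x", "y"], {"x": "one", "y": "two"})
        d = DistanceMatrix(["x", "y"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        with pytest.warns(UserWarning):
            assert diversity_summary(d, panel) == []


class TestNeighborJoining:
    def test_four_taxon_additive_worked_example(self):
        """d(A,B)=3 ... d(C,D)=9 must give ((A,B),(C,D)) with lengths
        A:1 B:2 C:4 D:5 and internal branch 3."""
        labels = list("ABCD")
        d = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert tree_bipartitions(tree) == {frozenset("CD")}
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}
        internal = [nd.edge.length for nd in tree.preorder_node_iter()
                    if nd is not tree.seed_node and not nd.is_leaf()]
        assert internal == [3.0]

    def test_three_taxa_closed_form(self):
        labels = list("ABC")
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(labels, d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        # a = (5+9-8)/2 = 3, b = (5+8-9)/2 = 2, c = (9+8-5)/2 = 6
        assert lengths == {"A": 3.0, "B": 2.0, "C": 6.0}

    def test_exact_recovery_on_random_additive_matrices(self, rng):
        """NJ is consistent: additive distances from random binary trees
        (n <= 12) are recovered with the exact topology."""
        for trial in range(100):
            n = int(rng.integers(4, 13))
            labels, d, true_bips = random_additive_matrix(n, rng)
            tree = nj_tree(DistanceMatrix(labels, d))
            assert tree_bipartitions(tree) == true_bips, (trial, n)

    def test_agrees_with_independent_nj_implementation(self, rng):
        """Cross-check topology against scikit-bio's NJ on random distances."""
        import io as _io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        labels = [f"t{i}" for i in range(8)]
        for _ in range(5):
            labels_, d, _bips = random_additive_matrix(8, rng)
            tree = nj_tree(DistanceMatrix(labels_, d))
            sk_tree = skbio_nj(SkbioDM(d, ids=labels_))
            sk_newick = _io.StringIO()
            sk_tree.write(sk_newick)
            assert tree_bipartitions(tree) == \
                newick_bipartitions_oracle(sk_newick.getvalue().strip())

    def test_invalid_distances_rejected(self):
        bad = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(DataError):
            nj_tree(DistanceMatrix(["a", "b"], bad))
        asym = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(DataError):
            nj_tree(DistanceMatrix(["a", "b", "c"], asym))


class TestBootstrap:
    def test_perfect_split_gets_full_support(self):
        # every column splits {a,b} vs {c,d}: the split survives any resample
        rows = {"a": [0] * 20, "b": [0] * 20, "c": [1] * 20, "d": [1] * 20}
        m = matrix_from_rows([rows[k] for k in "abcd"], list("abcd"))
        # add a little within-clade signal so NJ has positive branch lengths
        m.alleles[0, 1] = 2
        m.alleles[1, 3] = 3
        tree = bootstrap_support(m, n_replicates=50, seed=1)
        assert tree_bipartitions(tree) == {frozenset("cd")}
        supports = [nd.support for nd in tree.preorder_node_iter()
                    if nd is not tree.seed_node and not nd.is_leaf()]
        assert supports == [100.0]

    def test_supports_bounded_and_seed_reproducible(self, rng):
        accs = [f"a{i}" for i in range(6)]
        alleles = rng.integers(0, 4, size=(80, 6), dtype=np.uint8)
        m = GenotypeMatrix([("chr1", i + 1, "A") for i in range(80)], alleles, accs)
        t1 = bootstrap_support(m, n_replicates=30, seed=9)
        t2 = bootstrap_support(m, n_replicates=30, seed=9)
        s1 = sorted(nd.support for nd in t1.preorder_node_iter() if hasattr(nd, "support"))
        s2 = sorted(nd.support for nd in t2.preorder_node_iter() if hasattr(nd, "support"))
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)

    def test_accession_order_invariance(self, rng):
        accs = [f"a{i}" for i in range(5)]
        alleles = rng.integers(0, 4, size=(60, 5), dtype=np.uint8)
        m1 = GenotypeMatrix([("chr1", i + 1, "A") for i in range(60)], alleles, accs)
        perm = [3, 1, 4, 0, 2]
        m2 = GenotypeMatrix(m1.sites, alleles[:, perm], [accs[i] for i in perm])
        t1 = bootstrap_support(m1, n_replicates=40, seed=4)
        t2 = bootstrap_support(m2, n_replicates=40, seed=4)
        b1 = {frozenset(b): None for b in tree_bipartitions(t1)}
        b2 = {frozenset(b): None for b in tree_bipartitions(t2)}
        assert set(b1) == set(b2)

    def test_rejects_nonpositive_replicates(self):
        m = matrix_from_rows([[0, 1], [1, 0], [0, 0]], list("abc"))
        with pytest.raises(UsageError):
            bootstrap_support(m, n_replicates=0)


class TestRooting:
    def test_root_at_single_outgroup_leaf(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,OUT:4):1);")
        rooted = root_at_outgroup(tree, {"OUT"})
        kids = rooted.seed_node.child_nodes()
        sides = [frozenset(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
        assert frozenset({"OUT"}) in sides
        assert frozenset({"A", "B", "C"}) in sides

    def test_missing_outgroup_leaf_errors(self):
        tree = parse_tree("((A:1,B:1):1,C:1);")
        with pytest.raises(RootingError):
            root_at_outgroup(tree, {"ZZ"})

    def test_non_monophyletic_outgroup_errors_with_diagnostics(self):
        tree = parse_tree("((A:1,O1:1):1,(B:1,O2:1):1);")
        with pytest.raises(RootingError, match="not monophyletic"):
            root_at_outgroup(tree, {"O1", "O2"})


class TestCompareTrees:
    def test_identical_trees_are_congruent(self):
        t1 = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        rep = compare_trees(t1, t2)
        assert rep.rf_distance == 0 and rep.congruent

    def test_conflicting_quartets_have_rf_two(self):
        """((A,B),(C,D)) vs ((A,C),(B,D)): the two nontrivial splits conflict.

        Verified by exhaustive bipartition enumeration: each tree has one
        nontrivial split, they differ, so the symmetric difference is 2.
        """
        t1 = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_tree("((A:1,C:1):1,(B:1,D:1):1);")
        assert newick_bipartitions_oracle("((A,B),(C,D));") == {frozenset("CD")}
        assert newick_bipartitions_oracle("((A,C),(B,D));") == {frozenset("BD")}
        rep = compare_trees(t1, t2)
        assert rep.rf_distance == 2
        assert rep.splits_only_in_first == [frozenset("CD")]
        assert rep.splits_only_in_second == [frozenset("BD")]

    def test_rf_matches_dendropy_on_random_trees(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        for _ in range(20):
            n = int(rng.integers(4, 10))
            labels, d1, _ = random_additive_matrix(n, rng)
            _, d2, _ = random_additive_matrix(n, rng)
            t1 = nj_tree(DistanceMatrix(labels, d1))
            t2 = nj_tree(DistanceMatrix(labels, d2))
            rep = compare_trees(t1, t2)
            tns = dendropy.TaxonNamespace()
            dt1 = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                                    schema="newick", taxon_namespace=tns)
            dt2 = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                                    schema="newick", taxon_namespace=tns)
            dt1.encode_bipartitions()
            dt2.encode_bipartitions()
            assert rep.rf_distance == treecompare.symmetric_difference(dt1, dt2)

    def test_disjoint_leaf_sets_rejected(self):
        t1 = parse_tree("((A:1,B:1):1,C:1);")
        t2 = parse_tree("((X:1,Y:1):1,Z:1);")
        with pytest.raises(UsageError):
            compare_trees(t1, t2)

    def test_misplaced_species_flagged_by_leave_one_out(self):
        """Six species; X alone moves between two well-separated clades, so
        removing X (and only X) must reconcile the two trees."""
        species = ["A", "B", "C", "D", "E", "X"]
        accs = [f"{s.lower()}{i}" for s in species for i in (1, 2)]
        panel = SpeciesPanel(accs, {a: a[0].upper() for a in accs})

        def pair(s):
            return f"({s.lower()}1:1,{s.lower()}2:1):1"

        nuc = parse_tree(f"((({pair('A')},{pair('B')}):1,({pair('C')},{pair('X')}):1):1,"
                         f"({pair('D')},{pair('E')}):1);")
        org = parse_tree(f"((({pair('A')},{pair('B')}):1,{pair('C')}):1,"
                         f"(({pair('D')},{pair('X')}):1,{pair('E')}):1);")
        rep = compare_trees(nuc, org, panel)
        assert rep.rf_distance > 0
        assert rep.misplaced_species == ["X"]
        assert all(v == (True, True) for v in rep.monophyly.values())


class TestCollapse:
    def test_collapse_and_induced_species_tree(self):
        accs = ["a1", "a2", "b1", "b2", "o1"]
        panel = SpeciesPanel(accs, {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "o1": "O"},
                             outgroup={"o1"})
        tree = parse_tree("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,o1:5);")
        sp = collapse_to_species(tree, panel)
        assert {lf.taxon.label for lf in sp.leaf_node_iter()} == {"A", "B", "O"}

    def test_collapse_rejects_paraphyletic_species(self):
        accs = ["a1", "a2", "b1", "b2"]
        panel = SpeciesPanel(accs, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        tree = parse_tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        with pytest.raises(UsageError):
            collapse_to_species(tree, panel)
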