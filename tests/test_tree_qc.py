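import itertools
import random

import dendropy
import numpy as np
import pytest
from dendropy.simulate import treesim

from hybqc.core_io import parse_tree, tree_to_newick
from hybqc.tree_qc import (
    ClockCriteria,
    LocusTreeStats,
    TreeQCConfig,
    clock_stats,
    collapse_low_support,
    concordance_fraction,
    concordance_pies,
    flag_outlier_leaves,
    root_to_tip_lengths,
    select_clock_loci,
    tree_diameter,
)


def brute_diameter(tree: dendropy.Tree) -> float:
    """Independent oracle: dendropy's phylogenetic distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    best = 0.0
    for a, b in itertools.combinations(taxa, 2):
        best = max(best, pdm.distance(a, b))
    return best


def random_tree(seed: int, n: int) -> dendropy.Tree:
    t = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=random.Random(seed),
    )
    t.seed_node.edge.length = 0.0
    return t


class TestDiameter:
    def test_star_tree(self):
        assert tree_diameter(parse_tree("(A:1,B:1,C:1,D:1);")) == 2.0

    def test_caterpillar_path(self):
        assert tree_diameter(parse_tree("((A:1,B:1):1,C:3);")) == 5.0

    def test_two_leaves(self):
        assert tree_diameter(parse_tree("(A:0.3,B:0.2);")) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_trees(self):
        for seed in range(25):
            n = 4 + seed % 9  # 4..12 leaves
            t = random_tree(seed, n)
            assert tree_diameter(t) == pytest.approx(brute_diameter(t))

    def test_missing_lengths_named(self):
        t = parse_tree("((A:1,B:1):1,C:3);")
        for lf in t.leaf_node_iter():
            if lf.taxon.label == "B":
                lf.edge.length = None
        with pytest.raises(ValueError, match="B"):
            tree_diameter(t)


class TestOutlierLeaves:
    def test_symmetric_star_unflagged(self):
        flagged, pruned = flag_outlier_leaves(
            parse_tree("(A:1,B:1,C:1,D:1);"))
        assert flagged == []
        assert len(pruned.leaf_nodes()) == 4

    def test_long_branch_flagged_then_loop_stops(self):
        t = parse_tree("(A:10,B:1,C:1,D:1);")
        flagged, pruned = flag_outlier_leaves(t)
        assert flagged == ["A"]
        assert {lf.taxon.label for lf in pruned.leaf_nodes()} \
            == {"B", "C", "D"}

    def test_infinite_bound_flags_nothing(self):
        t = parse_tree("(A:10,B:1,C:1,D:1);")
        flagged, pruned = flag_outlier_leaves(
            t, TreeQCConfig(diameter_bound=float("inf")))
        assert flagged == []
        assert tree_to_newick(pruned) == tree_to_newick(t)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError, match="4 leaves"):
            flag_outlier_leaves(parse_tree("(A:1,B:1,C:1);"))


class TestCollapseLowSupport:
    def test_weak_clade_collapsed_strong_kept(self):
        t = parse_tree("((A:1,B:1)5:1,(C:1,D:1)95:1);")
        out = collapse_low_support(t, TreeQCConfig(support_cutoff=10))
        splits = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in out.preorder_internal_node_iter(exclude_seed_node=True)
        }
        assert splits == {frozenset({"C", "D"})}

    def test_boundary_support_is_contracted(self):
        # the rule is <=, so support exactly 10 goes
        t = parse_tree("((A:1,B:1)10:1,C:1);")
        out = collapse_low_support(t, TreeQCConfig(support_cutoff=10))
        assert len(out.seed_node.child_nodes()) == 3

    def test_full_support_unchanged(self):
        t = parse_tree("((A:1,B:1)100:1,(C:1,D:1)100:1);")
        out = collapse_low_support(t)
        assert tree_to_newick(out) == tree_to_newick(t)

    def test_unknown_support_retained(self):
        t = parse_tree("((A:1,B:1):1,C:1);")
        out = collapse_low_support(t)
        assert tree_to_newick(out) == tree_to_newick(t)

    def test_idempotent_and_leafset_stable(self):
        for seed in range(10):
            t = random_tree(seed, 8)
            rng = np.random.default_rng(seed)
            for nd in t.preorder_internal_node_iter(exclude_seed_node=True):
                nd.label = str(int(rng.integers(0, 101)))
            once = collapse_low_support(t)
            twice = collapse_low_support(once)
            assert tree_to_newick(once) == tree_to_newick(twice)
            assert {lf.taxon.label for lf in once.leaf_nodes()} \
                == {lf.taxon.label for lf in t.leaf_nodes()}
            n_internal = lambda x: sum(
                1 for _ in x.preorder_internal_node_iter())
            assert n_internal(once) <= n_internal(t)


class TestClockStats:
    def test_ultrametric_tree_has_zero_variance(self):
        t = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        s = clock_stats(t, t, TreeQCConfig(rooting="keep"))
        assert s.rtt_variance == pytest.approx(0.0, abs=1e-15)

    def test_worked_variance(self):
        # tip depths 1.5, 1.5, 2.0 -> sample variance 1/12
        t = parse_tree("((A:1,B:1):0.5,C:2);")
        depths = root_to_tip_lengths(t)
        assert sorted(depths) == pytest.approx([1.5, 1.5, 2.0])
        s = clock_stats(t, t, TreeQCConfig(rooting="keep"))
        assert s.rtt_variance == pytest.approx(1 / 12)
        assert s.tree_length == pytest.approx(4.5)
        assert s.n_taxa == 3

    def test_identical_topology_fully_concordant(self):
        sp = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        gene = parse_tree("((A:2,B:9):4,(C:1,D:5):2);")
        assert concordance_fraction(gene, sp) == 1.0

    def test_concordance_ignores_branch_lengths(self):
        sp = parse_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        gene = parse_tree("(((A:9,B:1):7,(C:2,D:1):1):3,(E:1,F:4):1);")
        assert concordance_fraction(gene, sp) == 1.0

    def test_disagreement_measured_after_pruning(self):
        sp = parse_tree("((A,B),(C,D),(E,F));")
        gene = parse_tree("((A,C),(B,D),(E,F));")
        # species splits on 6 taxa: AB, CD, EF; gene has only EF
        assert concordance_fraction(gene, sp) == pytest.approx(1 / 3)

    def test_too_few_shared_taxa(self):
        sp = parse_tree("((A,B),(C,D));")
        gene = parse_tree("((X,Y),(Z,A));")
        with pytest.raises(ValueError, match="shared"):
            concordance_fraction(gene, sp)


class TestSelectClockLoci:
    def make(self, locus, conc, rtt, length, n):
        return LocusTreeStats(locus, rtt, length, n, conc)

    def test_passing_locus_retained(self):
        retained, failures = select_clock_loci(
            [self.make("ok", 0.5, 0.001, 2.0, 30)])
        assert retained == ["ok"] and failures == {}

    def test_boundary_rtt_is_rejected(self):
        retained, failures = select_clock_loci(
            [self.make("edge", 0.5, 0.024, 2.0, 30)])
        assert retained == []
        assert failures["edge"] == ["rtt_variance"]

    def test_taxon_floor_is_inclusive(self):
        retained, _ = select_clock_loci(
            [self.make("exact", 0.5, 0.001, 2.0, 25)])
        assert retained == ["exact"]

    def test_all_failures_reported(self):
        _, failures = select_clock_loci(
            [self.make("bad", 0.05, 1.0, 0.05, 3)])
        assert failures["bad"] == [
            "concordance", "rtt_variance", "tree_length", "n_taxa"]

    def test_empty_input(self):
        assert select_clock_loci([]) == ([], {})


class TestConcordancePies:
    def test_identical_genes_all_concordant(self):
        sp = parse_tree("((A,B),(C,D));")
        genes = [parse_tree("((A,B),(C,D));") for _ in range(5)]
        pies = concordance_pies(genes, sp)
        assert len(pies) == 1
        assert (pies[0].n_concord, pies[0].n_conflict,
                pies[0].n_uninformative) == (5, 0, 0)

    def test_conflicting_gene_counted(self):
        sp = parse_tree("((A,B),(C,D));")
        gene = parse_tree("((A,C),(B,D));")
        (pie,) = concordance_pies([gene], sp)
        assert (pie.n_concord, pie.n_conflict, pie.n_uninformative) \
            == (0, 1, 0)

    def test_restriction_collapses_to_uninformative(self):
        sp = parse_tree("((A,B),(C,D));")
        gene = parse_tree("(A:1,B:1);")
        (pie,) = concordance_pies([gene], sp)
        assert (pie.n_concord, pie.n_conflict, pie.n_uninformative) \
            == (0, 0, 1)

    def test_counts_always_sum_to_gene_number(self):
        sp = parse_tree("(((A,B),(C,D)),((E,F),(G,H)));")
        genes = [
            parse_tree("(((A,C),(B,D)),((E,F),(G,H)));"),
            parse_tree("((A,B),(C,D));"),
            parse_tree("(((A,B),(C,D)),((E,G),(F,H)));"),
        ]
        for pie in concordance_pies(genes, sp):
            assert pie.n_concord + pie.n_conflict + pie.n_uninformative \
                == len(genes)

    def test_polytomy_is_uninformative_not_conflicting(self):
        sp = parse_tree("((A,B),(C,D));")
        gene = parse_tree("(A,B,C,D);")
        (pie,) = concordance_pies([gene], sp)
        assert (pie.n_concord, pie.n_conflict, pie.n_uninformative) \
            == (0, 0, 1)
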