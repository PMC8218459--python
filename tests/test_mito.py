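"""Haplotype collapsing, p-distances, parsimony networks, UPGMA, haplotype FST."""

import math

import networkx as nx
import numpy as np
import pytest

from ssrgbas import mito
from ssrgbas import simdata as sd
from ssrgbas.mito import Alignment


def make_alignment(seqs, pops=None):
    ids = [f"s{i+1}" for i in range(len(seqs))]
    pops = pops or {i: "p1" for i in ids}
    if isinstance(pops, list):
        pops = dict(zip(ids, pops))
    return Alignment(ids, list(seqs), pops)


class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        hs = mito.collapse_haplotypes(make_alignment(["ACGT"] * 10))
        assert hs.n_haplotypes == 1
        assert hs.frequencies["H1"] == 10

    def test_duplicate_changes_frequency_not_count(self):
        hs1 = mito.collapse_haplotypes(make_alignment(["ACGT", "ACGA"]))
        hs2 = mito.collapse_haplotypes(make_alignment(["ACGT", "ACGA", "ACGT"]))
        assert hs1.n_haplotypes == hs2.n_haplotypes == 2
        assert hs2.frequencies["H1"] == 2

    def test_strict_identity_keeps_n_distinct(self):
        hs = mito.collapse_haplotypes(make_alignment(["ACGT", "ACGN"]))
        assert hs.n_haplotypes == 2
        hs_wild = mito.collapse_haplotypes(make_alignment(["ACGT", "ACGN"]),
                                           wildcard_missing=True)
        assert hs_wild.n_haplotypes == 1

    def test_order_independent_up_to_labels(self):
        seqs = ["AAAA", "AAAT", "AATT", "AAAA", "AAAT"]
        hs1 = mito.collapse_haplotypes(make_alignment(seqs))
        hs2 = mito.collapse_haplotypes(make_alignment(seqs[::-1]))
        assert sorted(hs1.frequencies.values()) == sorted(hs2.frequencies.values())
        assert set(hs1.sequences.values()) == set(hs2.sequences.values())

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            mito.collapse_haplotypes(Alignment([], [], {}))

    def test_planted_group_structure(self):
        ids, seqs, pops = sd.simulate_coi_dataset(2, 10, 658, [0, 5], seed=4)
        hs = mito.collapse_haplotypes(Alignment(ids, seqs, pops))
        assert hs.n_haplotypes == 2


class TestPDistance:
    def test_identical_zero(self):
        D = mito.p_distance_matrix(["ACGT", "ACGT"])
        assert D.iloc[0, 1] == 0.0

    def test_single_difference_over_658(self):
        ids, seqs, _ = sd.simulate_coi_dataset(2, 1, 658, [1, 0], seed=1)
        D = mito.p_distance_matrix(seqs, ids)
        assert D.iloc[0, 1] == pytest.approx(100.0 / 658.0)

    def test_pairwise_deletion_hand_count(self):
        # 10 bp toy: one N column excluded -> 2 diffs over 9 compared sites
        a = "ACGTACGTAC"
        b = "ACGTNCGAAT"
        D = mito.p_distance_matrix([a, b], percent=False)
        assert D.iloc[0, 1] == pytest.approx(2 / 9)

    def test_symmetry_and_zero_diagonal(self):
        ids, seqs, _ = sd.simulate_coi_dataset(3, 2, 100, [2, 3, 4], seed=2)
        D = mito.p_distance_matrix(seqs, ids).values
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)


def oracle_parsimony_probability(j, L):
    """Independent re-coding of the finite-sites parsimony probability.

    Same published model algebra, written with explicit loops/logs rather
    than the package's closed-form expression.
    """
    if j == 0:
        return 1.0
    p = j / L
    if p >= 0.75:
        return 0.0
    d = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    log_prob = 0.0
    for _ in range(j):
        log_prob += math.log(d) - d - math.log(p)
    for _ in range(1):
        log_prob += (L - j) * (-d - math.log(1.0 - p))
    return math.exp(log_prob)


class TestParsimonyLimit:
    @pytest.mark.parametrize("L", [100, 658])
    def test_matches_independent_recursion(self, L):
        for j in range(1, 30):
            assert mito.parsimony_probability(j, L) == pytest.approx(
                oracle_parsimony_probability(j, L), rel=1e-9)
        limit = mito.parsimony_connection_limit(L, 0.95)
        oracle_limit = 1
        j = 2
        while oracle_parsimony_probability(j, L) >= 0.95:
            oracle_limit = j
            j += 1
        assert limit == oracle_limit

    def test_near_certain_confidence_collapses_to_single_steps(self):
        assert mito.parsimony_connection_limit(658, 0.999999) == 1

    def test_non_decreasing_in_length(self):
        limits = [mito.parsimony_connection_limit(L, 0.95)
                  for L in range(50, 1001, 50)]
        assert all(b >= a for a, b in zip(limits, limits[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            mito.parsimony_connection_limit(658, 1.5)


class TestNetwork:
    def test_single_step_edge(self):
        hs = mito.collapse_haplotypes(make_alignment(["AAAA", "AAAT"]))
        G = mito.build_parsimony_network(hs, limit=5)
        assert G.has_edge("H1", "H2")
        assert G.number_of_nodes() == 2

    def test_three_steps_insert_two_intermediates(self):
        hs = mito.collapse_haplotypes(make_alignment(["AAAAAA", "TTTAAA"]))
        G = mito.build_parsimony_network(hs, limit=3)
        assert G.number_of_nodes() == 4
        inferred = [n for n, d in G.nodes(data=True) if not d["observed"]]
        assert len(inferred) == 2
        assert nx.shortest_path_length(G, "H1", "H2") == 3

    def test_pairs_beyond_limit_stay_disconnected(self):
        ids, seqs, pops = sd.simulate_coi_dataset(2, 5, 658, [24, 0], seed=3,
                                                  within_variation=1)
        hs = mito.collapse_haplotypes(Alignment(ids, seqs, pops))
        limit = mito.parsimony_connection_limit(658, 0.95)
        G = mito.build_parsimony_network(hs, limit)
        comps = list(nx.connected_components(G))
        assert len(comps) == 2
        # planted divergence splits exactly along group lines
        for comp in comps:
            groups = {hs.seq_pops[s] for h in comp if h in hs.members
                      for s in hs.members[h]}
            assert len(groups) == 1

    def test_every_edge_is_one_mutational_step(self):
        ids, seqs, pops = sd.simulate_coi_dataset(3, 4, 200, [2, 3, 4], seed=5,
                                                  within_variation=1)
        hs = mito.collapse_haplotypes(Alignment(ids, seqs, pops))
        G = mito.build_parsimony_network(hs, limit=10)
        seq_of = nx.get_node_attributes(G, "sequence")
        for u, v in G.edges():
            assert sum(a != b for a, b in zip(seq_of[u], seq_of[v])) == 1

    def test_input_order_invariant_components(self):
        seqs = ["AAAA", "AAAT", "AATT", "CCCC"]
        hs1 = mito.collapse_haplotypes(make_alignment(seqs))
        hs2 = mito.collapse_haplotypes(make_alignment(seqs[::-1]))
        G1 = mito.build_parsimony_network(hs1, limit=2)
        G2 = mito.build_parsimony_network(hs2, limit=2)
        comp1 = sorted(len(c) for c in nx.connected_components(G1))
        comp2 = sorted(len(c) for c in nx.connected_components(G2))
        assert comp1 == comp2


class TestUpgma:
    def test_three_taxon_hand_tree(self):
        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float)
        t = mito.upgma_tree(D, ["A", "B", "C"])
        assert t.newick(with_support=False) == "(C:4,(A:1,B:1):3);"
        inner = [c for c in t.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(1.0)

    def test_four_taxon_hand_tree(self):
        ids = ["A", "B", "C", "D"]
        D = np.array([[0, 2, 10, 10],
                      [2, 0, 10, 10],
                      [10, 10, 0, 4],
                      [10, 10, 4, 0]], float)
        t = mito.upgma_tree(D, ids)
        parts = {frozenset(c.leaves()) for c in t.children}
        assert parts == {frozenset({"A", "B"}), frozenset({"C", "D"})}
        assert t.height == pytest.approx(5.0)

    def test_ultrametric_input_reproduced(self):
        # tree heights: (A,B) at 1, ((A,B),C) at 3, with D at 5
        D = np.array([[0, 2, 6, 10],
                      [2, 0, 6, 10],
                      [6, 6, 0, 10],
                      [10, 10, 10, 0]], float)
        t = mito.upgma_tree(D, ["A", "B", "C", "D"])

        def tree_dist(node, a, b):
            # distance through the tree between two leaves
            def path_heights(n, target, acc):
                if n.is_leaf:
                    return [acc] if n.name == target else None
                for c in n.children:
                    r = path_heights(c, target, acc + [n.height])
                    if r:
                        return r
                return None
            ha = path_heights(node, a, [])[0]
            hb = path_heights(node, b, [])[0]
            shared = [h for h in ha if h in hb]
            return 2 * min(shared) if shared else 2 * node.height

        for a, b, want in (("A", "B", 2), ("A", "C", 6), ("C", "D", 10)):
            assert tree_dist(t, a, b) == pytest.approx(want)

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(6)
        X = rng.random((6, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        t = mito.upgma_tree(D)
        heights = []

        def collect(n):
            if not n.is_leaf:
                heights.append(2 * n.height)
                for c in n.children:
                    collect(c)

        collect(t)
        Z = average(squareform(D, checks=False))
        np.testing.assert_allclose(sorted(heights), sorted(Z[:, 2]),
                                   atol=1e-9)

    def test_newick_parses_with_dendropy(self):
        import dendropy

        ids, seqs, pops = sd.simulate_coi_dataset(2, 4, 200, [3, 4], seed=7,
                                                  within_variation=1)
        hs = mito.collapse_haplotypes(Alignment(ids, seqs, pops))
        tree = mito.upgma_with_bootstrap(hs, n_bootstrap=20, seed=1)
        t = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(t.leaf_nodes()) == hs.n_haplotypes

    def test_homoplasy_free_alignment_gets_full_support(self):
        # deep, clean split: every bootstrap replicate recovers it
        seqs = ["A" * 30 + "C" * 10,
                "A" * 30 + "C" * 9 + "T",
                "G" * 30 + "C" * 10,
                "G" * 30 + "C" * 9 + "A"]
        hs = mito.collapse_haplotypes(make_alignment(seqs))
        tree = mito.upgma_with_bootstrap(hs, n_bootstrap=100, seed=2)
        supports = []

        def collect(n):
            if not n.is_leaf:
                if n.support is not None:
                    supports.append(n.support)
                for c in n.children:
                    collect(c)

        collect(tree)
        assert supports and min(supports) >= 95.0


class TestHaplotypeFst:
    def test_identical_compositions_zero(self):
        seqs = ["AAAA", "AATT"] * 4
        # both pops hold both haplotypes in equal proportion
        aln = make_alignment(seqs, ["p1", "p1", "p2", "p2"] * 2)
        hs = mito.collapse_haplotypes(aln)
        fst, p = mito.haplotype_pairwise_fst(hs, n_perm=99, seed=1)
        assert fst.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_haplotypes_give_one(self):
        aln = make_alignment(["AAAA"] * 5 + ["TTTT"] * 5,
                             ["p1"] * 5 + ["p2"] * 5)
        hs = mito.collapse_haplotypes(aln)
        fst, p = mito.haplotype_pairwise_fst(hs, n_perm=999, seed=1)
        assert fst.iloc[0, 1] == pytest.approx(1.0)
        # only 2 of C(10,5) label shuffles reproduce perfect sorting
        assert p.iloc[0, 1] < 0.05

    def test_hand_computed_mixture(self):
        # pop1 = {H1 x4}, pop2 = {H1 x2, H2 x2}
        # H_S = (0 + 0.5)/2 = 0.25; H_T = 1 - (0.75^2 + 0.25^2) = 0.375
        aln = make_alignment(["AAAA"] * 4 + ["AAAA", "AAAA", "TTTT", "TTTT"],
                             ["p1"] * 4 + ["p2"] * 4)
        hs = mito.collapse_haplotypes(aln)
        fst, _ = mito.haplotype_pairwise_fst(hs, n_perm=0, seed=1)
        assert fst.iloc[0, 1] == pytest.approx((0.375 - 0.25) / 0.375)

    def test_single_sequence_population_flagged(self):
        aln = make_alignment(["AAAA", "AATT", "TTTT"], ["p1", "p1", "p2"])
        hs = mito.collapse_haplotypes(aln)
        fst, p = mito.haplotype_pairwise_fst(hs, n_perm=0, seed=1)
        assert np.isnan(fst.iloc[0, 1])
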