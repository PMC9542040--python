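"""Tree handling: Newick parsing, pruning, Grafen heights, rho, correlation."""

import numpy as np
import pytest

from phylocrit import phylo, synth
from phylocrit.phylo import (
    correlation_matrix,
    grafen_heights,
    parse_newick,
    prune,
    rho_transform,
    write_newick,
)


def corr_of(newick, rho=None):
    t = grafen_heights(parse_newick(newick))
    if rho is not None:
        t = rho_transform(t, rho)
    return correlation_matrix(t)


class TestParse:
    def test_three_tips(self):
        t = parse_newick("((A,B),C);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        internal = sum(1 for n in t.dtree.preorder_node_iter() if not n.is_leaf())
        assert internal == 2

    def test_polytomy_retained(self):
        t = parse_newick("(A,B,C);")
        root_children = len(t.dtree.seed_node.child_nodes())
        assert root_children == 3

    def test_malformed_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_newick("((A,B),C;")

    def test_duplicate_labels_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A,A),C);")

    def test_round_trip_topology(self):
        """parse -> write -> parse preserves the correlation structure."""
        nwk = "(((A,B),(C,D)),(E,F));"
        c1 = corr_of(nwk)
        c2 = corr_of(write_newick(parse_newick(nwk)))
        order = [c2.species.index(s) for s in c1.species]
        np.testing.assert_allclose(c1.matrix, c2.matrix[np.ix_(order, order)])

    def test_input_branch_lengths_discarded(self):
        t = parse_newick("((A:3.1,B:0.2):9,C:1);")
        assert all(e.length is None for e in t.dtree.preorder_edge_iter())


class TestPrune:
    def test_simple(self):
        t = prune(parse_newick("((A,B),C);"), {"A", "B"})
        assert sorted(t.tip_labels) == ["A", "B"]

    def test_prune_to_all_is_identity(self):
        nwk = "(((A,B),C),D);"
        full = corr_of(nwk)
        kept = grafen_heights(prune(parse_newick(nwk), {"A", "B", "C", "D"}))
        same = correlation_matrix(kept).reorder(full.species)
        np.testing.assert_allclose(full.matrix, same.matrix)

    def test_induced_subtree(self):
        """Dropping B from (((A,B),C),D) leaves ((A,C),D)."""
        t = prune(parse_newick("(((A,B),C),D);"), {"A", "C", "D"})
        got = correlation_matrix(grafen_heights(t)).reorder(["A", "C", "D"])
        expect = corr_of("((A,C),D);").reorder(["A", "C", "D"])
        np.testing.assert_allclose(got.matrix, expect.matrix)

    def test_empty_keep_raises(self):
        with pytest.raises(ValueError, match="empty"):
            prune(parse_newick("(A,B);"), set())

    def test_missing_species_listed(self):
        with pytest.raises(ValueError, match="X"):
            prune(parse_newick("(A,B);"), {"A", "X"})


class TestGrafenHeights:
    def test_three_tip_heights(self):
        t = grafen_heights(parse_newick("((A,B),C);"))
        heights = {
            tuple(sorted(l.taxon.label for l in n.leaf_iter())): t.height(n)
            for n in t.dtree.preorder_node_iter()
            if not n.is_leaf()
        }
        assert heights[("A", "B", "C")] == pytest.approx(1.0)
        assert heights[("A", "B")] == pytest.approx(0.5)
        assert all(t.height(l) == 0.0 for l in t.dtree.leaf_node_iter())

    def test_cherry(self):
        t = grafen_heights(parse_newick("(A,B);"))
        for leaf in t.dtree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_balanced_four_tips(self):
        t = grafen_heights(parse_newick("((A,B),(C,D));"))
        for n in t.dtree.preorder_node_iter():
            if n.is_leaf():
                assert n.edge.length == pytest.approx(1.0 / 3.0)
            elif n.parent_node is not None:
                assert t.height(n) == pytest.approx(1.0 / 3.0)
                assert n.edge.length == pytest.approx(2.0 / 3.0)

    def test_single_tip_raises(self):
        with pytest.raises(ValueError):
            grafen_heights(parse_newick("(A);"))


class TestRhoTransform:
    def test_identity_at_one(self):
        base = corr_of("((A,B),C);")
        same = corr_of("((A,B),C);", rho=1.0)
        np.testing.assert_allclose(base.matrix, same.reorder(base.species).matrix)

    def test_internal_height_power(self):
        t = rho_transform(grafen_heights(parse_newick("((A,B),C);")), 0.4)
        hs = sorted(t.height(n) for n in t.dtree.preorder_node_iter() if not n.is_leaf())
        assert hs[0] == pytest.approx(0.5**0.4)  # ~0.7579

    def test_tip_branches_lengthen_for_rho_below_one(self):
        g = grafen_heights(synth.simulate_tree(12, seed=3))
        r = rho_transform(g, 0.4)
        for ng, nr in zip(g.dtree.preorder_node_iter(), r.dtree.preorder_node_iter()):
            if not ng.is_leaf() and ng.parent_node is not None:
                assert r.height(nr) > g.height(ng)

    def test_bad_rho_raises(self):
        g = grafen_heights(parse_newick("(A,B);"))
        with pytest.raises(ValueError):
            rho_transform(g, 0.0)

    def test_requires_heights(self):
        with pytest.raises(ValueError, match="heights"):
            rho_transform(parse_newick("(A,B);"), 0.4)


def path_sum_oracle(tree):
    """Brute-force C: sum of branch lengths from the root to the MRCA.

    Walks the explicit root->tip node paths pair by pair; independent of the
    postorder sweep in correlation_matrix.
    """
    tips = list(tree.dtree.leaf_node_iter())
    paths = {}
    for tip in tips:
        node, path = tip, []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[tip.taxon.label] = list(reversed(path))
    labels = [t.taxon.label for t in tips]
    n = len(labels)
    C = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                # ultrametric check: every root-to-tip path sums to 1
                depth = sum(nd.edge.length for nd in paths[labels[i]] if nd.parent_node is not None)
                assert depth == pytest.approx(1.0)
                continue
            shared = 0.0
            for a, b in zip(paths[labels[i]], paths[labels[j]]):
                if a is not b:
                    break
                if a.parent_node is not None:
                    shared += a.edge.length
            C[i, j] = shared
    return labels, C


class TestCorrelationMatrix:
    def test_star_tree_is_identity(self):
        c = corr_of("(A,B,C,D);")
        np.testing.assert_allclose(c.matrix, np.eye(4))

    def test_three_tip_values(self):
        c = corr_of("((A,B),C);").reorder(["A", "B", "C"])
        assert c.matrix[0, 1] == pytest.approx(0.5)
        assert c.matrix[0, 2] == pytest.approx(0.0)

    def test_three_tip_values_rho(self):
        c = corr_of("((A,B),C);", rho=0.4).reorder(["A", "B", "C"])
        assert c.matrix[0, 1] == pytest.approx(1.0 - 0.5**0.4)  # ~0.2421

    def test_requires_heights(self):
        with pytest.raises(ValueError, match="heights"):
            correlation_matrix(parse_newick("(A,B);"))

    @pytest.mark.parametrize("rho", [0.4, 1.0])
    def test_psd_on_random_trees(self, rho):
        """Cholesky succeeds for 200 random pure-birth trees."""
        rng = np.random.default_rng(77)
        for k in range(200):
            n = int(rng.integers(3, 41))
            t = rho_transform(grafen_heights(synth.simulate_tree(n, seed=1000 + k)), rho)
            C = correlation_matrix(t).matrix
            np.linalg.cholesky(C + 1e-12 * np.eye(n))

    def test_nested_clades_monotone(self):
        """Correlation never increases as the MRCA moves rootward."""
        c = corr_of("((((A,B),C),D),E);", rho=0.4).reorder(["A", "B", "C", "D", "E"])
        row = c.matrix[0]  # A against B, C, D, E: ever deeper MRCAs
        assert all(row[i] >= row[i + 1] for i in range(1, 4))

    @pytest.mark.parametrize("rho", [0.4, 1.0])
    def test_matches_path_sum_oracle(self, rho):
        """Exact agreement with root->MRCA path summation on small trees."""
        for seed in range(20):
            n = 3 + seed % 10  # up to 12 tips
            t = rho_transform(grafen_heights(synth.simulate_tree(n, seed=seed)), rho)
            got = correlation_matrix(t)
            labels, C_oracle = path_sum_oracle(t)
            got = got.reorder(labels)
            np.testing.assert_allclose(got.matrix, C_oracle, atol=1e-12)
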