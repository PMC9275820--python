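"""Likelihood engine, branch-length optimization, NNI search, supports."""

import math

import numpy as np
import pytest

from conftest import balanced_tree, enumerate_site_likelihood, random_instance
from paleotrx.data_io import MISSING, BinaryMatrix, PhyloTree
from paleotrx.substmodel import BinaryModel, transition_matrix
from paleotrx.treelik import (
    LikelihoodEngine,
    loglik,
    nni_neighbors,
    nni_search,
    optimize_branch_lengths,
    single_branch_tests,
    standard_bootstrap,
)


def simulate_tips(tree, model, n_genes, rng):
    """Forward-simulate tip states under the homogeneous model."""
    states = {}
    out = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = rng.random(n_genes) < model.pi[1]
        else:
            P = transition_matrix(model, node.edge.length or 0.0)
            parent = states[id(node.parent_node)]
            p1 = np.where(parent, P[1, 1], P[0, 1])
            states[id(node)] = rng.random(n_genes) < p1
        if node.is_leaf():
            out[node.taxon.label] = states[id(node)].astype(np.int8)
    return out


def matrix_from_tips(tips: dict) -> BinaryMatrix:
    taxa = list(tips)
    n = len(next(iter(tips.values())))
    return BinaryMatrix(
        taxa=taxa,
        gene_ids=[f"g{i}" for i in range(n)],
        states=np.array([tips[t] for t in taxa]),
    )


class TestLoglik:
    def test_star_tree_closed_form(self):
        # 3 tips all state 0, symmetric model, e^{-mu t} = 0.5 per branch:
        # L = 0.5 * 0.75^3 + 0.5 * 0.25^3 = 0.21875
        model = BinaryModel(pi=(0.5, 0.5))
        t = -math.log(0.5) / model.mu
        tree = PhyloTree.from_newick(f"(A:{t},B:{t},C:{t});")
        bm = BinaryMatrix(taxa=["A", "B", "C"], gene_ids=["g"], states=np.zeros((3, 1), dtype=np.int8))
        sl = loglik(tree, bm, model)
        assert math.exp(sl.per_site_loglik[0]) == pytest.approx(0.21875, abs=1e-12)

    def test_all_missing_site_is_uninformative(self, rng):
        tree, bm, model = random_instance(rng, 5)
        bm_q = BinaryMatrix(
            taxa=bm.taxa, gene_ids=["g"], states=np.full((5, 1), MISSING, dtype=np.int8)
        )
        assert loglik(tree, bm_q, model).per_site_loglik[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(15):
            tree, bm, model = random_instance(rng, int(rng.integers(3, 7)))
            sl = loglik(tree, bm, model)
            for j, gene in enumerate(bm.gene_ids):
                truth = enumerate_site_likelihood(
                    tree, {t: int(bm.row(t)[j]) for t in bm.taxa}, model
                )
                assert sl.per_site_loglik[j] == pytest.approx(math.log(truth), abs=1e-8)

    def test_rerooting_invariance(self, rng):
        tree, bm, model = random_instance(rng, 6, n_sites=10)
        base = loglik(tree, bm, model).total_loglik
        n_internal = sum(1 for _ in tree.dendropy_tree.preorder_internal_node_iter())
        for i in range(n_internal):
            rerooted = tree.copy()
            dt = rerooted.dendropy_tree
            node = list(dt.preorder_internal_node_iter())[i]
            dt.reroot_at_node(node, update_bipartitions=False, suppress_unifurcations=True)
            assert rerooted.total_length() == pytest.approx(tree.total_length(), abs=1e-9)
            assert loglik(rerooted, bm, model).total_loglik == pytest.approx(base, abs=1e-8)

    def test_missing_taxon_errors(self, rng):
        tree, bm, model = random_instance(rng, 4)
        extra = BinaryMatrix(
            taxa=bm.taxa + ["ghost"],
            gene_ids=bm.gene_ids,
            states=np.vstack([bm.states, np.zeros((1, bm.n_genes), dtype=np.int8)]),
        )
        with pytest.raises(ValueError, match="absent"):
            loglik(tree, extra, model)

    def test_category_posteriors_sum_to_one(self, rng):
        tree, bm, model = random_instance(rng, 5, n_sites=8)
        sl = loglik(tree, bm, model, return_category_posteriors=True)
        assert np.allclose(sl.per_site_category_posteriors.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_only_taxon_changes_nothing(self, rng):
        tree, bm, model = random_instance(rng, 5, n_sites=10)
        base = loglik(tree, bm, model).per_site_loglik
        # graft an all-? taxon onto the first pendant edge
        grown = tree.copy()
        dt = grown.dendropy_tree
        import dendropy

        leaf = next(dt.leaf_node_iter())
        parent = leaf.parent_node
        parent.remove_child(leaf)
        mid = dendropy.Node()
        mid.edge.length = leaf.edge.length / 2
        leaf.edge.length = leaf.edge.length / 2
        ghost = dendropy.Node(taxon=dendropy.Taxon(label="ghost"))
        ghost.edge.length = 0.3
        mid.add_child(leaf)
        mid.add_child(ghost)
        parent.add_child(mid)
        dt.taxon_namespace.add_taxon(ghost.taxon)
        grown2 = PhyloTree(dt)
        bm2 = BinaryMatrix(
            taxa=bm.taxa + ["ghost"],
            gene_ids=bm.gene_ids,
            states=np.vstack([bm.states, np.full((1, bm.n_genes), MISSING, dtype=np.int8)]),
        )
        assert np.allclose(loglik(grown2, bm2, model).per_site_loglik, base, atol=1e-10)


class TestOptimizeBranchLengths:
    @pytest.mark.parametrize("p_hat", [0.05, 0.15, 0.25, 0.35, 0.45])
    def test_two_taxon_closed_form(self, p_hat):
        n = 200
        ndiff = int(round(p_hat * n))
        states = np.zeros((2, n), dtype=np.int8)
        states[1, :ndiff] = 1
        bm = BinaryMatrix(taxa=["A", "B"], gene_ids=[f"g{i}" for i in range(n)], states=states)
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        opt, _ = optimize_branch_lengths(tree, bm, BinaryModel(pi=(0.5, 0.5)))
        expected = -0.5 * math.log(1 - 2 * ndiff / n)
        assert opt.total_length() == pytest.approx(expected, abs=1e-6)

    def test_identical_sequences_collapse(self):
        states = np.tile(np.array([[0, 1, 1, 0, 1]], dtype=np.int8), (3, 1))
        bm = BinaryMatrix(taxa=["A", "B", "C"], gene_ids=[f"g{i}" for i in range(5)], states=states)
        tree = PhyloTree.from_newick("(A:0.5,B:0.5,C:0.5);")
        opt, _ = optimize_branch_lengths(tree, bm, BinaryModel(pi=(0.5, 0.5)))
        assert opt.total_length() < 1e-6

    def test_idempotent_at_optimum(self, rng):
        model = BinaryModel(pi=(0.5, 0.5))
        tree = balanced_tree(8)
        tips = simulate_tips(tree, model, 200, rng)
        bm = matrix_from_tips(tips)
        once, lnl1 = optimize_branch_lengths(tree, bm, model)
        twice, lnl2 = optimize_branch_lengths(once, bm, model)
        assert lnl2 == pytest.approx(lnl1, abs=1e-4)
        assert lnl2 >= lnl1 - 1e-9  # never decreases


class TestNniSearch:
    def test_recovers_strong_split(self, rng):
        model = BinaryModel(pi=(0.5, 0.5))
        true = PhyloTree.from_newick("((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);")
        hits = 0
        for rep in range(3):
            bm = matrix_from_tips(simulate_tips(true, model, 300, rng))
            best, _ = nni_search(bm, model, random_starts=2, seed=rep)
            hits += frozenset({"A", "B"}) in best.bipartitions()
        assert hits == 3

    def test_deterministic_given_seed(self, rng):
        model = BinaryModel(pi=(0.5, 0.5))
        tree = balanced_tree(6)
        bm = matrix_from_tips(simulate_tips(tree, model, 150, rng))
        t1, l1 = nni_search(bm, model, random_starts=3, seed=11)
        t2, l2 = nni_search(bm, model, random_starts=3, seed=11)
        assert l1 == l2
        assert t1.rf_distance(t2) == 0

    def test_start_at_optimum_stays(self, rng):
        model = BinaryModel(pi=(0.5, 0.5))
        tree = balanced_tree(6)
        bm = matrix_from_tips(simulate_tips(tree, model, 400, rng))
        best, _ = nni_search(bm, model, start_tree=tree, seed=0)
        again, _ = nni_search(bm, model, start_tree=best, seed=0)
        assert again.rf_distance(best) == 0

    def test_neighbor_count(self):
        tree = balanced_tree(6)
        # unrooted 6-tip tree: 3 internal edges, 2 neighbors each
        assert len(nni_neighbors(tree)) == 6

    def test_too_few_taxa(self):
        bm = BinaryMatrix(taxa=["A", "B"], gene_ids=["g"], states=np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            nni_search(bm, BinaryModel())


@pytest.fixture(scope="module")
def strong_data():
    rng = np.random.default_rng(3)
    model = BinaryModel(pi=(0.5, 0.5))
    # short pendants, moderate internals: low homoplasy, crisp splits
    tree = PhyloTree.from_newick(
        "((A:0.05,B:0.05):0.2,(C:0.05,D:0.05):0.2,(E:0.05,F:0.05):0.2);"
    )
    bm = matrix_from_tips(simulate_tips(tree, model, 400, rng))
    return tree, bm, model


class TestBranchSupports:

    def test_bootstrap_single_replicate_binary(self, strong_data):
        tree, bm, model = strong_data
        bs = standard_bootstrap(bm, model, tree, replicates=1, seed=0)
        for vals in bs.supports.values():
            assert vals["stdboot"] in (0.0, 1.0)

    def test_bootstrap_strong_signal(self, strong_data):
        tree, bm, model = strong_data
        bs = standard_bootstrap(bm, model, tree, replicates=10, seed=1)
        focal = bs.supports[frozenset({"A", "B"})]
        assert focal["stdboot"] == 1.0

    def test_single_branch_tests_strong_signal(self, strong_data):
        tree, bm, model = strong_data
        sup = single_branch_tests(tree, bm, model, rell_replicates=1000, seed=2)
        focal = sup.supports[frozenset({"A", "B"})]
        assert focal["sh_alrt"] >= 80.0
        assert focal["abayes"] >= 0.90
        assert focal["param_alrt"] >= 0.95
        assert focal["lboot"] >= 0.90

    def test_degenerate_branch_symmetric(self):
        # constant characters: all three NNI configurations identical, so
        # aBayes = 1/3 and the parametric statistic is 0 (support 0.5)
        states = np.tile(np.array([[1, 0, 1, 0]], dtype=np.int8), (4, 1))
        bm = BinaryMatrix(taxa=["A", "B", "C", "D"], gene_ids=[f"g{i}" for i in range(4)], states=states)
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        sup = single_branch_tests(tree, bm, BinaryModel(pi=(0.5, 0.5)), rell_replicates=200, seed=0)
        vals = next(iter(sup.supports.values()))
        assert vals["abayes"] == pytest.approx(1 / 3, abs=0.01)
        assert vals["param_alrt"] <= 0.51
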