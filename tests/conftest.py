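"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the pruning machinery they check:
likelihoods and ancestral posteriors are computed by explicit enumeration
over all internal-node (and missing-tip) state assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paleotrx.data_io import MISSING, BinaryMatrix, PhyloTree
from paleotrx.substmodel import BinaryModel, transition_matrix


def enumerate_site_likelihood(
    tree: PhyloTree, states_by_tip: dict[str, int], model: BinaryModel
) -> float:
    """Brute-force site likelihood: sum over every assignment of states to
    internal nodes and missing tips, mixing over rate categories."""
    dt = tree.dendropy_tree
    nodes = list(dt.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    total = 0.0
    for r, w in model.rate_categories:
        Ps = {
            id(n): transition_matrix(model, n.edge.length or 0.0, r)
            for n in nodes
            if n.parent_node is not None
        }
        lik = 0.0
        for assign in itertools.product([0, 1], repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            leaf_choices = [
                [states_by_tip[n.taxon.label]]
                if states_by_tip[n.taxon.label] != MISSING
                else [0, 1]
                for n in leaves
            ]
            for leaf_states in itertools.product(*leaf_choices):
                smap = dict(amap)
                for n, s in zip(leaves, leaf_states):
                    smap[id(n)] = s
                p = model.pi[smap[id(dt.seed_node)]]
                for n in nodes:
                    if n.parent_node is not None:
                        p *= Ps[id(n)][smap[id(n.parent_node)], smap[id(n)]]
                lik += p
        total += w * lik
    return total


def enumerate_node_posterior(
    tree: PhyloTree, states_by_tip: dict[str, int], model: BinaryModel, node_label: str
) -> float:
    """Brute-force P(state = 1 at the labeled internal node | tip data)."""
    dt = tree.dendropy_tree
    nodes = list(dt.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    target = next(n for n in internals if n.label == node_label)
    num = 0.0
    den = 0.0
    for r, w in model.rate_categories:
        Ps = {
            id(n): transition_matrix(model, n.edge.length or 0.0, r)
            for n in nodes
            if n.parent_node is not None
        }
        for assign in itertools.product([0, 1], repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            leaf_choices = [
                [states_by_tip[n.taxon.label]]
                if states_by_tip[n.taxon.label] != MISSING
                else [0, 1]
                for n in leaves
            ]
            for leaf_states in itertools.product(*leaf_choices):
                smap = dict(amap)
                for n, s in zip(leaves, leaf_states):
                    smap[id(n)] = s
                p = model.pi[smap[id(dt.seed_node)]]
                for n in nodes:
                    if n.parent_node is not None:
                        p *= Ps[id(n)][smap[id(n.parent_node)], smap[id(n)]]
                den += w * p
                if amap[id(target)] == 1:
                    num += w * p
    return num / den


def random_instance(rng: np.random.Generator, n_tips: int, n_sites: int = 3):
    """A random (tree, matrix, model) triple for oracle comparisons."""
    from paleotrx.treelik import random_topology

    taxa = [f"T{i}" for i in range(n_tips)]
    tree = random_topology(taxa, rng)
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(0.05, 2.0))
    p1 = float(rng.uniform(0.2, 0.8))
    k = int(rng.integers(1, 4))
    if k == 1:
        cats = [(1.0, 1.0)]
    else:
        r = rng.uniform(0.2, 3.0, k)
        w = rng.dirichlet(np.ones(k))
        r = r / (w @ r)
        cats = list(zip(r.tolist(), w.tolist()))
    model = BinaryModel(pi=(1 - p1, p1), rate_categories=cats)
    states = rng.choice(
        np.array([0, 1, MISSING], dtype=np.int8),
        size=(n_tips, n_sites),
        p=[0.4, 0.4, 0.2],
    )
    bm = BinaryMatrix(
        taxa=taxa, gene_ids=[f"g{j}" for j in range(n_sites)], states=states
    )
    return tree, bm, model


def balanced_tree(n_tips: int, bl: float = 0.15) -> PhyloTree:
    """Balanced bifurcating tree with uniform branch lengths."""
    labels = [f"T{i}" for i in range(n_tips)]

    def build(lo, hi):
        if hi - lo == 1:
            return f"{labels[lo]}:{bl}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{bl}"

    half = n_tips // 2
    return PhyloTree.from_newick(f"({build(0, half)},{build(half, n_tips)});")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def cherry_setup():
    """Two-tip tree with e^{-mu t} = 0.5 under the symmetric model."""
    import math

    model = BinaryModel(pi=(0.5, 0.5))
    t = -math.log(0.5) / model.mu
    tree = PhyloTree.from_newick(f"(A:{t},B:{t});")
    return tree, model, t
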