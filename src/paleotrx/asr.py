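"""Empirical-Bayes marginal ancestral state reconstruction.

Given a fixed (constraint) topology, branch lengths and model parameters
are first fitted by maximum likelihood; ancestral posteriors are then the
marginal probabilities P(state at node v = s | data, MLEs), computed per
gene with inside/outside conditional-likelihood passes and mixed over
FreeRate categories with their posterior weights.  The posterior of the
"expressed" state (state 1) at a node is the Bayesian posterior
probability (BPP) reported in pie-chart form in comparative studies.

MAP (maximum a posteriori) states discretize the posteriors: state 1 when
BPP >= 0.5 (the tie at exactly 0.5 deliberately resolves to "expressed").
Assembled extant + ancestral binary transcriptomes feed the clustering
stage, and per-gene MAP states support counting independent expression
losses on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from paleotrx.data_io import MISSING, BinaryMatrix, PhyloTree
from paleotrx.substmodel import BinaryModel
from paleotrx.treelik import LikelihoodEngine, optimize_branch_lengths


@dataclass
class AncestralReconstruction:
    """Posterior P(expressed) and MAP states for internal nodes.

    ``posterior`` has shape (n_nodes, n_genes), rows matching ``node_ids``
    (internal-node labels of the constraint tree).  ``tip_posterior``
    holds, for taxa with missing data at a gene, the posterior implied by
    the rest of the tree (an imputation, flagged as such); for observed
    tips it equals the observed state.
    """

    node_ids: list[str]
    gene_ids: list[str]
    posterior: np.ndarray
    tree: PhyloTree
    taxa: list[str]
    tip_posterior: np.ndarray
    observed: np.ndarray  # original tip states incl. MISSING

    @property
    def map_states(self) -> np.ndarray:
        return (self.posterior >= 0.5).astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.posterior, index=self.node_ids, columns=self.gene_ids)


def marginal_posteriors(
    tree: PhyloTree,
    bm: BinaryMatrix,
    model: BinaryModel,
    optimize: bool = True,
) -> AncestralReconstruction:
    """Marginal ancestral posteriors on a fixed topology.

    Branch lengths are re-optimized by ML (unless ``optimize=False``, in
    which case the given lengths are trusted).  Unlabeled internal nodes
    are auto-labeled ``Node<k>`` in stable preorder numbering.  Per node
    and gene the two state posteriors sum to 1; a gene with only missing
    tips has posterior pi1 at every node.
    """
    work = tree.copy()
    work.label_internal_nodes()
    if optimize:
        work, _ = optimize_branch_lengths(work, bm, model)
    eng = LikelihoodEngine(work, bm)
    post = eng.node_marginals(model)  # (n_nodes, n_patterns, 2)
    p1 = post[:, eng.pattern_of_gene, 1]  # (n_nodes, n_genes)

    internal = [i for i in range(eng.n_nodes) if eng.children[i]]
    node_ids = [eng.nodes[i].label for i in internal]
    taxa = eng.taxa_order
    tip_rows = {eng.nodes[i].taxon.label: i for i in eng.tip_idx}
    observed = np.stack([bm.row(t) for t in taxa])
    tip_posterior = np.stack([p1[tip_rows[t]] for t in taxa])
    # observed tips: posterior equals the data
    obs_mask = observed != MISSING
    tip_posterior = np.where(obs_mask, observed.astype(float), tip_posterior)
    return AncestralReconstruction(
        node_ids=node_ids,
        gene_ids=list(bm.gene_ids),
        posterior=p1[internal],
        tree=work,
        taxa=list(taxa),
        tip_posterior=tip_posterior,
        observed=observed,
    )


def ancestral_transcriptomes(ar: AncestralReconstruction) -> BinaryMatrix:
    """Joint binary matrix of extant taxa plus ancestral nodes.

    Extant rows carry the observed states (including ``?``); ancestral
    rows carry MAP states.  Gene order is preserved.
    """
    states = np.vstack([ar.observed, ar.map_states])
    return BinaryMatrix(
        taxa=list(ar.taxa) + list(ar.node_ids),
        gene_ids=list(ar.gene_ids),
        states=states.astype(np.int8),
    )


def count_independent_losses(
    ar: AncestralReconstruction,
    gene: str,
) -> tuple[int, list[str]]:
    """Number of independent expression losses of one gene on the tree.

    A loss is a branch whose parent has MAP state 1 (expressed) and whose
    child has MAP state 0 (for tips: observed state 0); tips with missing
    data are excluded.  Returns the count and the child labels of the loss
    branches.
    """
    g = ar.gene_ids.index(gene)
    node_state = {n: int(s) for n, s in zip(ar.node_ids, ar.map_states[:, g])}
    tip_state = {t: int(s) for t, s in zip(ar.taxa, ar.observed[:, g])}
    losses: list[str] = []
    for node in ar.tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node.parent_node
        ps = node_state.get(parent.label)
        if ps is None:
            continue
        if node.is_leaf():
            cs = tip_state[node.taxon.label]
            if cs == MISSING:
                continue
            label = node.taxon.label
        else:
            cs = node_state[node.label]
            label = node.label
        if ps == 1 and cs == 0:
            losses.append(label)
    return len(losses), losses


def write_posteriors_tsv(ar: AncestralReconstruction, path) -> None:
    """Long-format TSV: node, gene, P(state 1)."""
    df = ar.to_frame().stack().rename("p_expressed").reset_index()
    df.columns = ["node", "gene", "p_expressed"]
    df.to_csv(path, sep="\t", index=False)
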