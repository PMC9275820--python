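"""Phylogenetic likelihood, branch-length optimization, NNI search, supports.

The likelihood engine implements Felsenstein pruning for two-state
characters under a FreeRate mixture: per site,

    L = sum_c w_c * L_c,    L_c = sum_s pi_s D_root(s | rate r_c)

where D_v(s) is the conditional likelihood of the data below node v given
state s at v.  Missing tips ('?') contribute the partial vector (1, 1).
Site patterns are compressed (unique columns with multiplicities), which
makes small-tree likelihoods essentially independent of gene count.

A complementary "outside" pass provides, for every branch, the site
likelihood as a function of that branch's length alone — used both for
fast per-branch Brent optimization and for marginal ancestral posteriors
(:mod:`paleotrx.asr`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from paleotrx.data_io import MISSING, BinaryMatrix, PhyloTree
from paleotrx.substmodel import BinaryModel

#: bounds for branch-length optimization (expected substitutions/site)
BL_MIN = 1e-8
BL_MAX = 10.0


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods for one (tree, model) pair."""

    per_site_loglik: np.ndarray
    total_loglik: float
    per_site_category_posteriors: np.ndarray | None = None


# ---------------------------------------------------------------------------
# pattern compression


def _compress_patterns(bm: BinaryMatrix, taxa_order: list[str]):
    """Unique site patterns, their counts, and the gene -> pattern map.

    Compression is done once per matrix in its native taxon order and
    cached; a requested taxon order only permutes the pattern rows (the
    column identity of a site does not depend on row order)."""
    cache = getattr(bm, "_pattern_cache", None)
    if cache is None:
        patterns, inverse, counts = np.unique(
            bm.states, axis=1, return_inverse=True, return_counts=True
        )
        cache = (patterns, inverse.ravel(), counts.astype(float))
        object.__setattr__(bm, "_pattern_cache", cache)
    patterns, inverse, counts = cache
    idx = [bm.taxa.index(t) for t in taxa_order]
    return patterns[idx], inverse, counts


# ---------------------------------------------------------------------------
# the engine


class LikelihoodEngine:
    """Array-backed pruning engine for one (tree, matrix) pair.

    Nodes are indexed in postorder with the root last.  ``edge_len[v]`` is
    the length of the branch above node ``v`` (unused for the root).
    Pattern ``weights`` default to the gene multiplicities and may be
    replaced to express bootstrap resamples.
    """

    def __init__(
        self,
        tree: PhyloTree,
        bm: BinaryMatrix,
        weights: np.ndarray | None = None,
    ):
        dt = tree.dendropy_tree
        self.tree = tree
        self.bm = bm
        nodes = list(dt.postorder_node_iter())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.edge_len = np.zeros(self.n_nodes)
        tip_labels = []
        self.tip_idx = []
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                self.parent[i] = self.index[id(n.parent_node)]
                self.children[self.parent[i]].append(i)
                self.edge_len[i] = n.edge.length if n.edge.length is not None else 0.0
            if n.is_leaf():
                tip_labels.append(n.taxon.label)
                self.tip_idx.append(i)
        missing_taxa = set(tip_labels) - set(bm.taxa)
        if missing_taxa:
            raise ValueError(f"tree tips absent from matrix: {sorted(missing_taxa)}")
        extra = set(bm.taxa) - set(tip_labels)
        if extra:
            raise ValueError(f"matrix taxa absent from tree: {sorted(extra)}")
        self.taxa_order = tip_labels
        patterns, self.pattern_of_gene, counts = _compress_patterns(bm, tip_labels)
        self.n_patterns = patterns.shape[1]
        self.weights = counts if weights is None else np.asarray(weights, float)
        # tip partials: one-hot, or (1,1) for missing
        self.tip_partials = np.empty((len(tip_labels), self.n_patterns, 2))
        for row, states in enumerate(patterns):
            tp = np.empty((self.n_patterns, 2))
            tp[:, 0] = (states == 0) | (states == MISSING)
            tp[:, 1] = (states == 1) | (states == MISSING)
            self.tip_partials[row] = tp
        self._tip_row = {v: r for r, v in enumerate(self.tip_idx)}
        # per-node rescaling guards against underflow; with two states and
        # modest tree depth doubles are safe, so skip it on small trees
        self.use_scaling = len(tip_labels) > 40

    # -- core passes -------------------------------------------------------

    def _edge_P(self, model: BinaryModel, transposed: bool = False) -> np.ndarray:
        """Transition matrices per node and rate category: (n_nodes, k, 2, 2).

        With ``transposed=True`` the child-state axis comes first, the form
        needed to push a child partial up to its parent by matmul.
        """
        pi = np.asarray(model.pi)
        rates = model.rates
        decay = np.exp(-model.mu * self.edge_len[:, None] * rates[None, :])
        P = np.broadcast_to(pi, (self.n_nodes, len(rates), 2, 2)).copy()
        P += decay[:, :, None, None] * (np.eye(2) - pi[None, :])
        return np.ascontiguousarray(P.swapaxes(2, 3)) if transposed else P

    def _rescale(self, acc, s):
        mx = acc.max(axis=2)
        mx = np.where(mx > 0, mx, 1.0)
        return acc / mx[:, :, None], s + np.log(mx)

    def _down_pass(self, model: BinaryModel):
        """Conditional (subtree) likelihoods per node, with log-scaling.

        All rate categories are propagated together; arrays are indexed
        (node, category, pattern, state).  ``msg[v]`` is the message v
        sends to its parent (D[v] pushed through P_v), sharing v's scale.
        """
        PT = self._edge_P(model, transposed=True)
        k = model.n_categories
        shape = (self.n_nodes, k, self.n_patterns, 2)
        D = np.empty(shape)
        logsD = np.zeros(shape[:3])
        msg = np.empty(shape)
        for v in range(self.n_nodes):
            if not self.children[v]:
                D[v] = self.tip_partials[self._tip_row[v]][None, :, :]
            else:
                acc = msg[self.children[v][0]].copy()
                s = logsD[self.children[v][0]].copy()
                for c in self.children[v][1:]:
                    acc *= msg[c]
                    s += logsD[c]
                if self.use_scaling:
                    acc, s = self._rescale(acc, s)
                D[v] = acc
                logsD[v] = s
            if v != self.root:
                msg[v] = D[v] @ PT[v]
        return D, logsD, msg, self._edge_P(model)

    def _up_pass(self, model: BinaryModel, D, logsD, msg, P):
        """Outside arrays: B[v](s_parent) excludes subtree(v); A[v](s_v)
        includes the branch above v.  Root prior pi enters through A[root].
        """
        pi = np.asarray(model.pi)
        A = np.empty_like(D)
        logsA = np.zeros_like(logsD)
        B = np.empty_like(D)
        logsB = np.zeros_like(logsD)
        A[self.root] = pi
        for v in range(self.n_nodes - 1, -1, -1):
            if not self.children[v]:
                continue
            for c in self.children[v]:
                acc = A[v].copy()
                s = logsA[v].copy()
                for w in self.children[v]:
                    if w != c:
                        acc = acc * msg[w]
                        s = s + logsD[w]
                if self.use_scaling:
                    acc, s = self._rescale(acc, s)
                B[c] = acc
                logsB[c] = s
                A[c] = B[c] @ P[c]
                logsA[c] = logsB[c]
        return A, logsA, B, logsB

    # -- likelihood --------------------------------------------------------

    def pattern_logliks(self, model: BinaryModel, return_posteriors: bool = False):
        """Per-pattern log-likelihood under the rate mixture.

        Optionally also returns per-pattern category posteriors (patterns x
        k), each row summing to 1.
        """
        pi = np.asarray(model.pi)
        D, logsD, _, _ = self._down_pass(model)
        lik = D[self.root] @ pi
        cat_loglik = (np.log(np.maximum(lik, 1e-300)) + logsD[self.root]).T
        logw = np.log(model.weights)
        m = cat_loglik.max(axis=1)
        mix = m + np.log(np.exp(cat_loglik - m[:, None]) @ model.weights)
        if not return_posteriors:
            return mix, None
        post = np.exp(cat_loglik + logw[None, :] - mix[:, None])
        post /= post.sum(axis=1, keepdims=True)
        return mix, post

    def total_loglik(self, model: BinaryModel) -> float:
        pat, _ = self.pattern_logliks(model)
        return float(self.weights @ pat)

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector back to per-gene order."""
        return per_pattern[self.pattern_of_gene]

    # -- per-branch likelihood profile --------------------------------------

    def _branch_context(self, model: BinaryModel):
        """Inside/outside arrays so the likelihood profile of any single
        branch length is a cheap closed form."""
        D, logsD, msg, P = self._down_pass(model)
        A, logsA, B, logsB = self._up_pass(model, D, logsD, msg, P)
        return (D, logsD, B, logsB)

    def _branch_loglik(self, model: BinaryModel, ctx, v: int, t: float) -> float:
        """Total log-likelihood with branch above v set to ``t`` (others
        fixed), computed from cached inside/outside arrays."""
        pi = np.asarray(model.pi)
        D, logsD, B, logsB = ctx
        decay = np.exp(-model.mu * model.rates * t)  # (k,)
        P = np.broadcast_to(pi, (len(decay), 2, 2)).copy()
        P += decay[:, None, None] * (np.eye(2) - pi[None, :])
        lik = ((B[v] @ P) * D[v]).sum(axis=2)
        cat = (np.log(np.maximum(lik, 1e-300)) + logsB[v] + logsD[v]).T
        m = cat.max(axis=1)
        mix = m + np.log(np.exp(cat - m[:, None]) @ model.weights)
        return float(self.weights @ mix)

    def _optimize_sweep(self, model: BinaryModel, xatol: float = 1e-9) -> float:
        """One exact coordinate-ascent sweep over all branch lengths.

        Inside partials are computed once (they stay valid when edges are
        visited root-outward, since no edge below the current one has been
        touched); outside partials are propagated incrementally, with
        sibling messages refreshed against already-updated lengths.  Every
        1-D optimization therefore sees the exact conditional profile and
        the total log-likelihood is non-decreasing.  Returns the total
        log-likelihood at the new lengths.
        """
        pi = np.asarray(model.pi)
        rates = model.rates
        eye = np.eye(2)
        D, logsD, msg, _ = self._down_pass(model)
        k = model.n_categories
        A = np.empty((self.n_nodes, k, self.n_patterns, 2))
        logsA = np.zeros((self.n_nodes, k, self.n_patterns))
        A[self.root] = pi

        def P_of(t):
            decay = np.exp(-model.mu * rates * t)
            return pi[None, None, :] + decay[:, None, None] * (eye - pi[None, :])

        for u in range(self.n_nodes - 1, -1, -1):
            kids = self.children[u]
            if not kids:
                continue
            for v in kids:
                # sibling messages against current (possibly updated) lengths
                acc = A[u].copy()
                s = logsA[u].copy()
                for w in kids:
                    if w == v:
                        continue
                    acc = acc * (D[w] @ P_of(self.edge_len[w]).swapaxes(1, 2))
                    s = s + logsD[w]
                if self.use_scaling:
                    acc, s = self._rescale(acc, s)
                B, logsB = acc, s
                base = logsB + logsD[v]

                def neg(t, v=v, B=B, base=base):
                    lik = ((B @ P_of(t)) * D[v]).sum(axis=2)
                    cat = (np.log(np.maximum(lik, 1e-300)) + base).T
                    m = cat.max(axis=1)
                    mix = m + np.log(np.exp(cat - m[:, None]) @ model.weights)
                    return -float(self.weights @ mix)

                res = minimize_scalar(
                    neg, bounds=(BL_MIN, BL_MAX), method="bounded",
                    options={"xatol": xatol},
                )
                if -res.fun > -neg(self.edge_len[v]):
                    self.edge_len[v] = float(res.x)
                A[v] = B @ P_of(self.edge_len[v])
                logsA[v] = logsB
        return self.total_loglik(model)

    def write_lengths(self) -> PhyloTree:
        """Copy the engine's branch lengths back onto a fresh tree."""
        out = self.tree.copy()
        for node, src in zip(out.dendropy_tree.postorder_node_iter(), self.nodes):
            i = self.index[id(src)]
            if node.parent_node is not None:
                node.edge.length = float(self.edge_len[i])
        return out

    def node_marginals(self, model: BinaryModel) -> np.ndarray:
        """Marginal posterior P(state | data) at every node, mixed over rate
        categories; shape (n_nodes, n_patterns, 2)."""
        D, logsD, msg, P = self._down_pass(model)
        A, logsA, B, logsB = self._up_pass(model, D, logsD, msg, P)
        joint = np.maximum(A * D, 1e-300)  # (node, k, pattern, state)
        logw = np.log(model.weights)
        logj = np.log(joint) + (logsA + logsD)[..., None] + logw[None, :, None, None]
        m = logj.max(axis=(1, 3), keepdims=True)
        post = np.exp(logj - m).sum(axis=1)
        post /= post.sum(axis=2, keepdims=True)
        return post


# ---------------------------------------------------------------------------
# public operations


def loglik(
    tree: PhyloTree,
    bm: BinaryMatrix,
    model: BinaryModel,
    return_category_posteriors: bool = False,
) -> SiteLikelihoods:
    """Total and per-site log-likelihood of a binary matrix on a tree.

    Sites with only missing data have likelihood 1 (log-likelihood 0).
    Under the reversible model the result is invariant to the position of
    the root.
    """
    eng = LikelihoodEngine(tree, bm)
    pat, post = eng.pattern_logliks(model, return_posteriors=return_category_posteriors)
    per_site = eng.expand(pat)
    return SiteLikelihoods(
        per_site_loglik=per_site,
        total_loglik=float(per_site.sum()),
        per_site_category_posteriors=None if post is None else post[eng.pattern_of_gene],
    )


def optimize_branch_lengths(
    tree: PhyloTree,
    bm: BinaryMatrix,
    model: BinaryModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
    weights: np.ndarray | None = None,
    _engine: LikelihoodEngine | None = None,
) -> tuple[PhyloTree, float]:
    """Maximum-likelihood branch lengths by round-robin per-branch search.

    Each branch is optimized in turn by bounded Brent search on
    [1e-8, 10] using cached inside/outside partials, so every accepted
    update increases the total log-likelihood; sweeps repeat until the
    gain over a full sweep is below ``tol``.

    Returns (tree with ML lengths, total log-likelihood).
    """
    eng = _engine or LikelihoodEngine(tree, bm, weights=weights)
    prev = eng.total_loglik(model)
    if not np.isfinite(prev):
        raise ValueError("non-finite starting likelihood")
    cur = prev
    for _ in range(max_sweeps):
        cur = eng._optimize_sweep(model)
        if not np.isfinite(cur):
            bad = int(np.argmax(~np.isfinite(eng.edge_len)))
            raise ValueError(f"non-finite likelihood at branch above node {bad}")
        if cur - prev < tol:
            break
        prev = cur
    return eng.write_lengths(), float(cur)


# ---------------------------------------------------------------------------
# NNI moves and tree search


def _deroot(tree: PhyloTree) -> PhyloTree:
    """Return an unrooted copy (root trifurcation) of the tree."""
    t = tree.copy().dendropy_tree
    root = t.seed_node
    if len(root.child_nodes()) == 2:
        t.collapse_basal_bifurcation()
    return PhyloTree(t)


def _internal_edges(dt: dendropy.Tree) -> list[dendropy.Node]:
    """Internal edges, identified by their child node, in postorder."""
    out = []
    for node in dt.postorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            out.append(node)
    return out


def _subtree_min_tip(node: dendropy.Node) -> str:
    return min(l.taxon.label for l in node.leaf_iter())


def _nni_moves(base: PhyloTree) -> list[tuple[PhyloTree, list]]:
    """NNI rearrangements of an unrooted tree, with the touched nodes.

    For each internal edge (u, v) with children (a, b) of v, the fixed
    exchange partner c is u's other neighbor (smallest tip label first for
    determinism); the two rearrangements swap a<->c and b<->c.  The
    returned node handles (v, u, a, c) locate the branches whose lengths
    the swap perturbs, for local re-optimization.
    """
    out: list[tuple[PhyloTree, list]] = []
    dt = base.dendropy_tree
    n_internal = len(_internal_edges(dt))
    for ei in range(n_internal):
        for which in (0, 1):
            nb = base.copy()
            ndt = nb.dendropy_tree
            v = _internal_edges(ndt)[ei]
            u = v.parent_node
            sibs = [c for c in u.child_nodes() if c is not v]
            if not sibs:
                continue
            c = min(sibs, key=_subtree_min_tip)
            a = sorted(v.child_nodes(), key=_subtree_min_tip)[which]
            u.remove_child(c)
            v.remove_child(a)
            u.add_child(a)
            v.add_child(c)
            out.append((PhyloTree(ndt), [v, u, a, c]))
    return out


def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees one nearest-neighbor interchange away (unrooted sense)."""
    return [t for t, _ in _nni_moves(_deroot(tree))]


def _screen_neighbor(
    nb: PhyloTree,
    local_nodes: list,
    bm: BinaryMatrix,
    model: BinaryModel,
    weights: np.ndarray | None,
) -> float:
    """Approximate a neighbor's log-likelihood by re-optimizing only the
    branches around the interchange (other lengths inherited)."""
    eng = LikelihoodEngine(nb, bm, weights=weights)
    ctx = eng._branch_context(model)
    for node in local_nodes:
        v = eng.index.get(id(node))
        if v is None or v == eng.root:
            continue

        def neg(t, v=v):
            return -eng._branch_loglik(model, ctx, v, t)

        res = minimize_scalar(
            neg, bounds=(BL_MIN, BL_MAX), method="bounded", options={"xatol": 1e-6}
        )
        if -res.fun > -neg(eng.edge_len[v]):
            eng.edge_len[v] = float(res.x)
    return eng.total_loglik(model)


def nj_start_tree(bm: BinaryMatrix) -> PhyloTree:
    """Neighbor-joining starting tree from pairwise CFN distances.

    Pairwise mismatch proportions over unambiguous sites are corrected by
    d = -0.5 ln(1 - 2p) (capped near saturation) and clustered by the
    standard neighbor-joining algorithm with lexicographic tie-breaking,
    so the start tree is fully deterministic.
    """
    n = bm.n_taxa
    S = bm.states
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (S[i] != MISSING) & (S[j] != MISSING)
            p = float(np.mean(S[i][ok] != S[j][ok])) if ok.any() else 0.0
            p = min(p, 0.4999)
            D[i, j] = D[j, i] = -0.5 * math.log(1.0 - 2.0 * p)
    # standard NJ agglomeration on the distance matrix
    newicks = {i: f"{bm.taxa[i]}" for i in range(n)}
    active = list(range(n))
    dist = {(min(i, j), max(i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}

    def d(i, j):
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best, best_q = (i, j), q
        i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(li, BL_MIN), max(lj, BL_MIN)
        newicks[nxt] = f"({newicks[i]}:{li:.10g},{newicks[j]}:{lj:.10g})"
        for k in active:
            if k not in (i, j):
                dist[(min(k, nxt), max(k, nxt))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    a, b, c = active
    la = max(0.5 * (d(a, b) + d(a, c) - d(b, c)), BL_MIN)
    lb = max(0.5 * (d(a, b) + d(b, c) - d(a, c)), BL_MIN)
    lc = max(0.5 * (d(a, c) + d(b, c) - d(a, b)), BL_MIN)
    newick = f"({newicks[a]}:{la:.10g},{newicks[b]}:{lb:.10g},{newicks[c]}:{lc:.10g});"
    tree = PhyloTree.from_newick(newick)
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = min(max(node.edge.length or BL_MIN, BL_MIN), BL_MAX)
    return tree


def random_topology(taxa: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random unrooted topology by stepwise random addition order."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    order = list(taxa)
    rng.shuffle(order)
    newick = f"({order[0]}:0.1,{order[1]}:0.1,{order[2]}:0.1);"
    tree = PhyloTree.from_newick(newick)
    for label in order[3:]:
        dt = tree.dendropy_tree
        edges = [n for n in dt.postorder_node_iter() if n.parent_node is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent_node
        parent.remove_child(target)
        mid = dendropy.Node()
        mid.edge.length = 0.1
        target.edge.length = 0.1
        mid.add_child(target)
        leaf = dendropy.Node(taxon=dendropy.Taxon(label=label))
        leaf.edge.length = 0.1
        mid.add_child(leaf)
        parent.add_child(mid)
        dt.taxon_namespace.add_taxon(leaf.taxon)
        tree = PhyloTree(dt)
    tree.dendropy_tree.update_taxon_namespace()
    return tree


def nni_search(
    bm: BinaryMatrix,
    model: BinaryModel,
    start_tree: PhyloTree | None = None,
    random_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-4,
    weights: np.ndarray | None = None,
    climb_tol: float = 1e-3,
) -> tuple[PhyloTree, float]:
    """Maximum-likelihood topology by steepest-ascent NNI hill climbing.

    Candidate neighbors are screened by re-optimizing only the branches
    around the interchange; the best improving move is applied and the
    tree's lengths re-optimized, until no move improves the
    log-likelihood by more than ``tol`` (a final full-precision length
    optimization follows).  With ``start_tree`` given, that single start
    is used; otherwise ``random_starts`` random-addition trees are
    climbed and the best result returned.  Deterministic given the seed.
    """
    if bm.n_taxa < 4:
        raise ValueError("tree search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    if start_tree is not None:
        starts = [_deroot(start_tree)]
    else:
        # a neighbor-joining tree plus random-addition topologies
        starts = [nj_start_tree(bm)] + [
            random_topology(list(bm.taxa), rng) for _ in range(max(0, random_starts - 1))
        ]
    best_tree, best_lnl = None, -np.inf
    for st in starts:
        tree, lnl = optimize_branch_lengths(st, bm, model, tol=climb_tol, weights=weights)
        while True:
            cand, cand_lnl = None, lnl + tol
            for nb, local in _nni_moves(tree):
                screened = _screen_neighbor(nb, local, bm, model, weights)
                if screened > cand_lnl:
                    cand, cand_lnl = nb, screened
            if cand is None:
                break
            tree, lnl = optimize_branch_lengths(
                cand, bm, model, tol=climb_tol, weights=weights
            )
        tree, lnl = optimize_branch_lengths(tree, bm, model, weights=weights)
        if lnl > best_lnl:
            best_tree, best_lnl = tree, lnl
    return best_tree, float(best_lnl)


# ---------------------------------------------------------------------------
# branch supports


@dataclass
class BranchSupport:
    """Per-branch support values keyed by bipartition (smaller tip side).

    Values: ``stdboot`` and ``lboot`` are proportions in [0,1]; ``sh_alrt``
    is a percent; ``abayes`` and ``param_alrt`` are probabilities.
    """

    supports: dict[frozenset, dict[str, float]] = field(default_factory=dict)

    def merge(self, other: "BranchSupport") -> "BranchSupport":
        out = BranchSupport({k: dict(v) for k, v in self.supports.items()})
        for k, v in other.supports.items():
            out.supports.setdefault(k, {}).update(v)
        return out

    def table(self):
        import pandas as pd

        rows = []
        for bip, vals in self.supports.items():
            rows.append({"bipartition": "|".join(sorted(bip)), **vals})
        return pd.DataFrame(rows)


def standard_bootstrap(
    bm: BinaryMatrix,
    model: BinaryModel,
    tree: PhyloTree,
    replicates: int = 100,
    seed: int | None = None,
) -> BranchSupport:
    """Nonparametric bootstrap support for the branches of ``tree``.

    Each replicate resamples genes with replacement and re-runs the NNI
    search (started from ``tree``); support for a bipartition is the
    proportion of replicate ML trees containing it.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    eng = LikelihoodEngine(tree, bm)
    n_genes = bm.n_genes
    target = tree.bipartitions()
    counts = {bip: 0 for bip in target}
    for _ in range(replicates):
        gene_counts = rng.multinomial(n_genes, np.full(n_genes, 1.0 / n_genes))
        pat_w = np.bincount(
            eng.pattern_of_gene, weights=gene_counts, minlength=eng.n_patterns
        )
        rep_tree, _ = nni_search(
            bm, model, start_tree=tree, weights=pat_w, seed=int(rng.integers(2**31))
        )
        rep_bips = rep_tree.bipartitions()
        for bip in target:
            if bip in rep_bips:
                counts[bip] += 1
    return BranchSupport(
        {bip: {"stdboot": counts[bip] / replicates} for bip in target}
    )


def _nni_configs_for_edge(tree: PhyloTree, edge_index: int) -> list[PhyloTree]:
    """The original tree plus its two NNI rearrangements around one edge."""
    base = _deroot(tree)
    configs = [base]
    dt = base.dendropy_tree
    for which in (0, 1):
        nb = base.copy()
        ndt = nb.dendropy_tree
        v = _internal_edges(ndt)[edge_index]
        u = v.parent_node
        sibs = [c for c in u.child_nodes() if c is not v]
        c = min(sibs, key=_subtree_min_tip)
        a = sorted(v.child_nodes(), key=_subtree_min_tip)[which]
        u.remove_child(c)
        v.remove_child(a)
        u.add_child(a)
        v.add_child(c)
        configs.append(PhyloTree(ndt))
    return configs


def single_branch_tests(
    tree: PhyloTree,
    bm: BinaryMatrix,
    model: BinaryModel,
    rell_replicates: int = 1000,
    seed: int | None = None,
) -> BranchSupport:
    """aLRT-family supports for every internal branch of the ML tree.

    For each internal branch the three NNI configurations around it are
    branch-length-optimized; with ordered log-likelihoods l1 >= l2 >= l3:

    * parametric aLRT: statistic 2(l1-l2) against the 1/2 chi2_0 + 1/2
      chi2_1 mixture; reported as support 1-p.
    * aBayes: exp(l1) / sum_i exp(l_i) in log-space.
    * SH-aLRT: percent of RELL replicates in which the observed statistic
      exceeds the centered replicate statistic.
    * LBoot: proportion of RELL replicates where the original best
      configuration remains best.
    """
    rng = np.random.default_rng(seed)
    base, base_lnl = optimize_branch_lengths(_deroot(tree), bm, model)
    base_sl = loglik(base, bm, model)
    n_internal = len(_internal_edges(base.dendropy_tree))
    n_genes = bm.n_genes
    out = BranchSupport()
    for ei in range(n_internal):
        configs = _nni_configs_for_edge(base, ei)
        site_logl = np.empty((3, n_genes))
        totals = np.empty(3)
        site_logl[0] = base_sl.per_site_loglik
        totals[0] = base_sl.total_loglik
        for i, cfg in enumerate(configs[1:], start=1):
            opt, lnl = optimize_branch_lengths(cfg, bm, model)
            sl = loglik(opt, bm, model)
            site_logl[i] = sl.per_site_loglik
            totals[i] = sl.total_loglik
        order = np.argsort(-totals)
        l1, l2, l3 = totals[order]
        stat = 2.0 * (l1 - l2)
        # parametric aLRT: mixture 0.5*chi2_0 + 0.5*chi2_1
        p_param = 0.5 * chi2.sf(stat, df=1) + (0.5 if stat <= 0 else 0.0)
        param_alrt = 1.0 - p_param
        # aBayes in log space
        shifted = totals - totals.max()
        abayes = float(np.exp(shifted[order[0]]) / np.exp(shifted).sum())
        # RELL resampling (paired across configurations)
        counts = rng.multinomial(
            n_genes, np.full(n_genes, 1.0 / n_genes), size=rell_replicates
        )
        rep_tot = counts @ site_logl.T  # (B, 3)
        centered = rep_tot - totals[None, :]
        part = np.partition(centered, -2, axis=1)
        rep_stat = 2.0 * (part[:, -1] - part[:, -2])
        sh_alrt = 100.0 * float(np.mean(stat > rep_stat))
        lboot = float(np.mean(np.argmax(rep_tot, axis=1) == order[0]))
        # identify the bipartition of this edge on the original tree
        v = _internal_edges(configs[0].dendropy_tree)[ei]
        tips = frozenset(l.taxon.label for l in v.leaf_iter())
        all_tips = frozenset(configs[0].tip_labels)
        other = all_tips - tips
        bip = tips if (len(tips), sorted(tips)) <= (len(other), sorted(other)) else other
        out.supports[bip] = {
            "sh_alrt": sh_alrt,
            "abayes": abayes,
            "param_alrt": param_alrt,
            "lboot": lboot,
        }
    return out
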