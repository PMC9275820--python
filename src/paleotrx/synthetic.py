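"""Synthetic data with the structure the pipeline assumes.

The generator emulates a comparative uterine-transcriptome study: a
23-taxon amniote tree (a monotreme sister to the therians, marsupial and
eutherian clades, and sauropsid outgroups), placenta-type regimes with a
configurable number of independent origins of the focal (non-invasive,
epitheliochorial) regime, binary expression characters evolving under the
two-state model with FreeRate heterogeneity, TPM-scale observations that
invert the binary encoding exactly, and bulk mixtures of cell-type
signatures for deconvolution.

Convergence is modeled as a regime-dependent equilibrium frequency: a
"convergent" gene evolves with its stationary frequency of the expressed
state shifted by ``regime_effect`` on every branch inside the focal
regime.  This single knob produces the signature of interest — unrelated
lineages sharing a regime drift toward the same expression profile, which
pulls gene-expression trees away from the species tree and makes extant
and ancestral transcriptomes cluster by regime.

Every simulator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from paleotrx.data_io import MISSING, BinaryMatrix, ExpressionMatrix, PhyloTree
from paleotrx.deconv import SignatureMatrix
from paleotrx.substmodel import BinaryModel

#: Regime labels (placenta types, in order of increasing invasiveness
#: after the oviparous state).
REGIMES = ("oviparous", "epitheliochorial", "endotheliochorial", "hemochorial")

#: The focal convergent regime (non-invasive placentas).
FOCAL_REGIME = "epitheliochorial"

# 23-tip amniote topology: sauropsid outgroups (bird + squamates, among
# them a reproductively bimodal skink), platypus sister to the therians,
# three marsupials, and 13 eutherians spanning the placenta types.
AMNIOTE23_NEWICK = (
    "((Chicken,(Anolis,((Saiphos_oviparous,Saiphos_viviparous),"
    "(Chalcides,Zootoca)))),(Platypus,((Opossum,(Dunnart,Wallaby)),"
    "(Armadillo,(((Cow,Pig),(Horse,(Dog,Cat))),(Bat,((Rabbit,"
    "(Guinea_pig,(Mouse,Rat))),(Macaque,Human))))))));"
)


#: Focal-regime (epitheliochorial) clades of the stored amniote tree:
#: the marsupials, two non-invasive ungulate lineages, and the viviparous
#: skink — four independent origins on distant branches.
AMNIOTE_FOCAL_CLADES = (
    ("Opossum", "Dunnart", "Wallaby"),
    ("Cow", "Pig"),
    ("Horse",),
    ("Saiphos_viviparous",),
)


def amniote_regimes(tree: PhyloTree) -> tuple[dict[str, str], list[str]]:
    """The fixed placenta-type regime map of the stored amniote tree.

    Marks every node inside the four focal clades as epitheliochorial and
    everything else as hemochorial background; returns (label -> regime,
    child labels of the four origin branches).  The tree must carry the
    stored 23 tip labels (internal nodes are labeled if needed).
    """
    work = tree
    work.label_internal_nodes(prefix="Anc")
    dt = work.dendropy_tree
    dt.is_rooted = True

    def label(n):
        return n.taxon.label if n.is_leaf() else n.label

    focal_ids: set[int] = set()
    origins: list[str] = []
    for clade in AMNIOTE_FOCAL_CLADES:
        if len(clade) > 1:
            node = dt.mrca(taxon_labels=list(clade))
        else:
            node = next(l for l in dt.leaf_node_iter() if l.taxon.label == clade[0])
        origins.append(label(node))
        for d in node.preorder_iter():
            focal_ids.add(id(d))
    regime_of = {
        label(n): (FOCAL_REGIME if id(n) in focal_ids else "hemochorial")
        for n in dt.preorder_node_iter()
    }
    return regime_of, sorted(origins)


def stretch_origin_branches(
    tree: PhyloTree, origin_labels: list[str], factor: float = 3.0
) -> None:
    """Lengthen the branches on which the focal regime originates.

    Regime origins are ancient, long-lived lineages; a long origin branch
    both gives regime-responsive genes time to converge and decouples the
    ancestor above the origin from its converged descendants, which is
    what makes independent losses identifiable in reconstruction.
    Modifies the tree in place.
    """
    targets = set(origin_labels)
    for node in tree.dendropy_tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        if label in targets and node.parent_node is not None:
            node.edge.length = (node.edge.length or 0.0) * factor


@dataclass
class SimulationConfig:
    """Generating parameters for the binary-character simulator."""

    n_taxa: int = 23
    n_genes: int = 2000
    pi1: float = 0.5
    rate_categories: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.2, 0.3), (1.0, 0.4), (2.5, 0.3)]
    )
    frac_convergent: float = 0.0
    regime_effect: float = 0.0
    missing_rate: float = 0.02
    flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pi1 < 1:
            raise ValueError("pi1 must be in (0,1)")
        for name in ("frac_convergent", "missing_rate", "flip_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.regime_effect < 0:
            raise ValueError("regime_effect must be >= 0")
        # normalize the mixture: weights to sum 1, rates to mean 1, so
        # branch lengths keep their substitutions-per-site interpretation
        w = sum(wc for _, wc in self.rate_categories)
        if w <= 0:
            raise ValueError("rate-category weights must be positive")
        cats = [(r, wc / w) for r, wc in self.rate_categories]
        mean = sum(r * wc for r, wc in cats)
        self.rate_categories = [(r / mean, wc) for r, wc in cats]

    def model(self) -> BinaryModel:
        return BinaryModel(
            pi=(1 - self.pi1, self.pi1), rate_categories=list(self.rate_categories)
        )


@dataclass
class SimulatedTruth:
    """Complete generating record, sufficient to score any estimate."""

    true_tree: PhyloTree
    node_states: dict[str, np.ndarray]  # label -> per-gene states (pre-noise)
    regime_of: dict[str, str]  # node/tip label -> regime
    origin_labels: list[str]  # child labels of regime-origin branches
    convergent: np.ndarray  # per-gene flag
    gene_rates: np.ndarray
    config: SimulationConfig


def simulate_tree(
    n_taxa: int = 23,
    model: str = "fixed_amniote",
    seed: int = 0,
    depth: float = 0.15,
) -> PhyloTree:
    """A species tree with branch lengths in expected substitutions/site.

    ``fixed_amniote`` returns the stored 23-tip amniote topology with
    every branch set to ``depth``; ``birth_death`` simulates a random
    topology (birth rate 1, death rate 0) and rescales branch lengths to
    a mean of ``depth``.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if model == "fixed_amniote":
        tree = PhyloTree.from_newick(AMNIOTE23_NEWICK)
        for node in tree.dendropy_tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = depth
        tree.label_internal_nodes(prefix="Anc")
        return tree
    if model == "birth_death":
        from dendropy.model import birthdeath

        dt = birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_taxa,
            rng=random.Random(seed),
        )
        for i, leaf in enumerate(dt.leaf_node_iter()):
            leaf.taxon.label = f"T{i + 1}"
        lens = [
            e.length for e in dt.preorder_edge_iter() if e.head_node.parent_node and e.length
        ]
        scale = depth / np.mean(lens)
        for e in dt.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
        tree = PhyloTree(dt)
        tree.label_internal_nodes(prefix="Anc")
        return tree
    raise ValueError(f"unknown tree model {model!r}")


def simulate_regimes(
    tree: PhyloTree,
    origins: int = 4,
    seed: int = 0,
    focal: str = FOCAL_REGIME,
    background: str = "hemochorial",
) -> tuple[dict[str, str], list[str]]:
    """Assign regimes with ``origins`` independent transitions into the
    focal regime.

    Picks that many disjoint, non-root clades (uniformly at random among
    feasible choices) and assigns the focal regime to every node inside
    them; everything else keeps the background regime.  Returns
    (label -> regime for every node, child labels of the origin branches).
    """
    if origins < 1:
        raise ValueError("origins must be >= 1")
    rng = np.random.default_rng(seed)
    work = tree.copy()
    work.label_internal_nodes(prefix="Anc")
    dt = work.dendropy_tree
    nodes = [n for n in dt.preorder_node_iter() if n.parent_node is not None]

    def label(n):
        return n.taxon.label if n.is_leaf() else n.label

    def tipset(n):
        return frozenset(l.taxon.label for l in n.leaf_iter())

    all_tips = tipset(dt.seed_node)
    chosen: list = []
    covered: set = set()
    order = list(rng.permutation(len(nodes)))
    for i in order:
        n = nodes[i]
        ts = tipset(n)
        if ts & covered or ts == all_tips:
            continue
        if len(all_tips - (covered | ts)) < 1:
            continue
        chosen.append(n)
        covered |= ts
        if len(chosen) == origins:
            break
    if len(chosen) < origins:
        raise ValueError(
            f"cannot place {origins} disjoint regime origins on this tree"
        )
    regime_of = {}
    focal_nodes = set()
    for n in chosen:
        for d in n.preorder_iter():
            focal_nodes.add(id(d))
    for n in dt.preorder_node_iter():
        regime_of[label(n)] = focal if id(n) in focal_nodes else background
    origin_labels = sorted(label(n) for n in chosen)
    return regime_of, origin_labels


def simulate_binary(
    tree: PhyloTree,
    config: SimulationConfig,
    regime_of: dict[str, str] | None = None,
    focal: str = FOCAL_REGIME,
) -> tuple[BinaryMatrix, SimulatedTruth]:
    """Evolve binary characters down the tree.

    Every gene draws a rate from the FreeRate mixture; a fraction
    ``frac_convergent`` of genes are regime-responsive and use the
    shifted equilibrium frequency pi1 + regime_effect (clamped to (0,1))
    on branches whose child node is in the focal regime.  Tip states are
    then perturbed: flipped with probability ``flip_noise`` and masked to
    ``?`` with probability ``missing_rate``.  Truth records the pre-noise
    states of every node.
    """
    rng = np.random.default_rng(config.seed)
    work = tree.copy()
    work.label_internal_nodes(prefix="Anc")
    dt = work.dendropy_tree
    G = config.n_genes
    rates = np.array([r for r, _ in config.rate_categories])
    weights = np.array([w for _, w in config.rate_categories])
    gene_rates = rates[rng.choice(len(rates), size=G, p=weights)]
    convergent = rng.random(G) < config.frac_convergent
    pi1 = config.pi1
    pi1_shift = float(np.clip(pi1 + config.regime_effect, 1e-3, 1 - 1e-3))

    def label(n):
        return n.taxon.label if n.is_leaf() else n.label

    node_states: dict[str, np.ndarray] = {}
    state_of: dict[int, np.ndarray] = {}
    for n in dt.preorder_node_iter():
        if n.parent_node is None:
            s = (rng.random(G) < pi1).astype(np.int8)
        else:
            in_focal = regime_of is not None and regime_of[label(n)] == focal
            p1 = np.where(convergent & in_focal, pi1_shift, pi1)
            mu = 1.0 / (2.0 * p1 * (1.0 - p1))
            t = n.edge.length or 0.0
            decay = np.exp(-mu * gene_rates * t)
            parent = state_of[id(n.parent_node)]
            prob1 = p1 + (parent - p1) * decay
            s = (rng.random(G) < prob1).astype(np.int8)
        state_of[id(n)] = s
        node_states[label(n)] = s.copy()

    taxa = work.tip_labels
    states = np.stack([state_of[id(n)] for n in dt.leaf_node_iter()])
    if config.flip_noise > 0:
        flip = rng.random(states.shape) < config.flip_noise
        states = np.where(flip, 1 - states, states).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(states.shape) < config.missing_rate
        states = np.where(miss, MISSING, states).astype(np.int8)
    bm = BinaryMatrix(
        taxa=taxa,
        gene_ids=[f"g{i + 1}" for i in range(G)],
        states=states,
        threshold_used=2.0,
    )
    truth = SimulatedTruth(
        true_tree=work,
        node_states=node_states,
        regime_of=dict(regime_of) if regime_of else {label(n): "" for n in dt.preorder_node_iter()},
        origin_labels=[],
        convergent=convergent,
        gene_rates=gene_rates,
        config=config,
    )
    return bm, truth


def simulate_tpm(
    bm: BinaryMatrix,
    seed: int = 0,
    threshold: float = 2.0,
    loc_expressed: float = math.log(16.0),
    loc_silent: float = math.log(0.2),
    scale: float = 1.0,
) -> ExpressionMatrix:
    """TPM-scale observations consistent with the binary states.

    State 1 draws from a lognormal truncated to [threshold, inf), state 0
    from one truncated to [0, threshold); ``?`` becomes a missing value.
    By construction ``encode_binary(simulate_tpm(bm)) == bm`` exactly.
    """
    rng = np.random.default_rng(seed)
    states = bm.states.T.astype(float)  # genes x samples
    vals = np.full(states.shape, np.nan)

    def draw_trunc(mask, loc, below):
        idx = np.argwhere(mask)
        need = len(idx)
        out = np.empty(need)
        filled = np.zeros(need, dtype=bool)
        while not filled.all():
            todo = ~filled
            draw = rng.lognormal(loc, scale, size=int(todo.sum()))
            ok = draw < threshold if below else draw >= threshold
            pos = np.flatnonzero(todo)[ok]
            out[pos] = draw[ok]
            filled[pos] = True
        vals[tuple(idx.T)] = out

    draw_trunc(states == 1, loc_expressed, below=False)
    draw_trunc(states == 0, loc_silent, below=True)
    return ExpressionMatrix(
        gene_ids=list(bm.gene_ids),
        sample_ids=list(bm.taxa),
        values=vals,
    )


def simulate_bulk(
    sig: SignatureMatrix,
    fractions: np.ndarray,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Bulk profiles as signature × fractions with lognormal noise.

    ``fractions`` is (n_samples, n_cell_types), rows on the simplex;
    ``noise`` is the log-scale sigma of multiplicative noise.  Returns the
    bulk expression table and the true fractions.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim == 1:
        fr = fr[None, :]
    if np.any(fr < 0) or not np.allclose(fr.sum(axis=1), 1.0):
        raise ValueError("fractions must lie on the simplex")
    rng = np.random.default_rng(seed)
    clean = sig.values @ fr.T  # genes x samples
    if noise > 0:
        clean = clean * rng.lognormal(0.0, noise, size=clean.shape)
    expr = ExpressionMatrix(
        gene_ids=list(sig.marker_gene_ids),
        sample_ids=[f"bulk{i + 1}" for i in range(fr.shape[0])],
        values=clean,
    )
    return expr, fr


def reference_signature(
    n_cell_types: int = 4,
    markers_per_type: int = 25,
    expression: float = 50.0,
    background: float = 1.0,
    seed: int = 0,
) -> SignatureMatrix:
    """A synthetic cell-type signature with clean fivefold markers.

    Each cell type gets ``markers_per_type`` genes expressed at
    ``expression`` (with mild lognormal spread) against a low background
    in all other types, comfortably passing the marker rule.
    """
    rng = np.random.default_rng(seed)
    cts = [f"cell{c + 1}" for c in range(n_cell_types)]
    genes, vals = [], []
    for c in range(n_cell_types):
        for g in range(markers_per_type):
            row = background * rng.lognormal(0.0, 0.2, size=n_cell_types)
            row[c] = expression * rng.lognormal(0.0, 0.2)
            genes.append(f"marker_{cts[c]}_{g + 1}")
            vals.append(row)
    return SignatureMatrix(
        marker_gene_ids=genes,
        cell_types=cts,
        values=np.asarray(vals),
        marker_of=[g.split("_")[1] for g in genes],
        fold_threshold=5.0,
        expression_threshold=2.0,
    )


# ---------------------------------------------------------------------------
# presets


def preset(name: str, seed: int = 0, n_genes: int | None = None) -> dict:
    """Named study conditions bundling tree, regimes, matrix, and truth.

    * ``null`` — no convergent genes; the baseline for topology recovery.
    * ``convergence`` — 30% convergent genes with a strong regime shift
      and four independent origins of the focal regime.
    * ``rora-loss`` — background genes plus one focal regime-tracking gene
      ("RORA") not expressed in any focal-regime tip, for loss counting.
    * ``deconv`` — synthetic signature and noisy bulk mixtures.
    """
    rng = np.random.default_rng(seed)
    if name == "deconv":
        sig = reference_signature(seed=seed)
        fr = rng.dirichlet(np.ones(len(sig.cell_types)), size=6)
        bulk, true_fr = simulate_bulk(sig, fr, noise=0.1, seed=int(rng.integers(2**31)))
        return {"signature": sig, "bulk": bulk, "true_fractions": true_fr}

    if name == "null":
        tree = simulate_tree()
        cfg = SimulationConfig(n_genes=n_genes or 2000, seed=seed)
        bm, truth = simulate_binary(tree, cfg)
        return {"tree": tree, "matrix": bm, "truth": truth, "config": cfg}
    if name == "convergence":
        # shallow tree with a near-fixated shifted equilibrium: convergence
        # onto the focal regime is fast on regime branches while background
        # reconstruction stays accurate, the regime-dominant signature the
        # pipeline is meant to detect
        tree = simulate_tree(depth=0.08)
        regime_of, origins = amniote_regimes(tree)
        stretch_origin_branches(tree, origins)
        cfg = SimulationConfig(
            n_genes=n_genes or 2000,
            pi1=0.35,
            frac_convergent=0.5,
            regime_effect=0.62,
            seed=seed,
        )
        bm, truth = simulate_binary(tree, cfg, regime_of=regime_of)
        truth.origin_labels = origins
        truth.regime_of = regime_of
        return {"tree": tree, "matrix": bm, "truth": truth, "config": cfg,
                "regime_of": regime_of, "origins": origins}
    if name == "rora-loss":
        tree = simulate_tree()
        regime_of, origins = amniote_regimes(tree)
        stretch_origin_branches(tree, origins)
        cfg = SimulationConfig(
            n_genes=n_genes or 300, pi1=0.35, seed=seed, missing_rate=0.02
        )
        bm, truth = simulate_binary(tree, cfg)
        # focal gene: expressed everywhere except in focal-regime tips
        focal_states = np.array(
            [0 if regime_of[t] == FOCAL_REGIME else 1 for t in bm.taxa], dtype=np.int8
        )
        states = np.column_stack([bm.states, focal_states])
        bm2 = BinaryMatrix(
            taxa=bm.taxa,
            gene_ids=bm.gene_ids + ["RORA"],
            states=states,
            threshold_used=2.0,
        )
        truth.origin_labels = origins
        truth.regime_of = regime_of
        return {"tree": tree, "matrix": bm2, "truth": truth, "config": cfg,
                "regime_of": regime_of, "origins": origins, "focal_gene": "RORA"}
    raise ValueError(f"unknown preset {name!r}")
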