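"""Non-parametric tree topology tests via RELL resampling.

Candidate trees are compared on the same data by resampling estimated
log-likelihoods (RELL): per-site log-likelihoods are computed once at the
ML parameter estimates of each tree, and bootstrap replicates re-weight
sites by multinomial counts without any re-optimization.  The same
replicate weights are used for every tree (paired resampling), so all
test statistics are comparable and reproducible given the seed.

Implemented tests: BP-RELL (bootstrap proportion), one-sided KH, SH
(maximum over the candidate set, centered), their variance-weighted
variants WKH/WSH, expected likelihood weights (c-ELW), and the
approximately unbiased (AU) test via multiscale bootstrap.  A tree is in
the 95% confidence set of a test when its p-value is >= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from paleotrx.data_io import BinaryMatrix, PhyloTree
from paleotrx.substmodel import BinaryModel
from paleotrx.treelik import loglik, optimize_branch_lengths

#: default multiscale-bootstrap scale grid for the AU test
AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass
class TopoTestResult:
    """Per-tree topology-test report (rows ordered as the input tree list)."""

    table: pd.DataFrame

    def confidence_set(self, test: str, alpha: float = 0.05) -> list[bool]:
        """True for trees retained in the (1-alpha) confidence set."""
        return list(self.table[test] >= alpha)


def site_loglik_matrix(
    trees: list[PhyloTree],
    bm: BinaryMatrix,
    model: BinaryModel,
    optimize: bool = True,
) -> np.ndarray:
    """Per-site log-likelihood of each candidate tree (trees x sites).

    Branch lengths of each tree are ML-optimized on the original data
    first (RELL then holds them fixed)."""
    rows = []
    for tree in trees:
        if optimize:
            tree, _ = optimize_branch_lengths(tree, bm, model)
        rows.append(loglik(tree, bm, model).per_site_loglik)
    mat = np.asarray(rows)
    if len({r.shape for r in mat}) > 1:  # pragma: no cover - shape guard
        raise ValueError("site count mismatch across trees")
    return mat


def rell_matrix(
    site_logl: np.ndarray,
    replicates: int = 100000,
    seed: int | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """RELL replicate totals: (replicates x trees).

    Replicate b draws multinomial site counts n_b (with total round(n *
    scale)) and totals sum_site n_b(site) * logL_tree(site); the same
    counts are applied to every tree."""
    n_trees, n_sites = site_logl.shape
    if n_trees < 1:
        raise ValueError("need at least one tree")
    rng = np.random.default_rng(seed)
    n_draw = max(1, int(round(n_sites * scale)))
    counts = rng.multinomial(n_draw, np.full(n_sites, 1.0 / n_sites), size=replicates)
    # rescale so replicate totals are comparable to the original scale
    return (counts @ site_logl.T) * (n_sites / n_draw)


def _best_fractions(rep: np.ndarray) -> np.ndarray:
    """Indicator of being the best tree per replicate, ties split evenly."""
    is_best = rep >= rep.max(axis=1, keepdims=True) - 1e-12
    return is_best / is_best.sum(axis=1, keepdims=True)


def run_tests(
    site_logl: np.ndarray,
    replicates: int = 100000,
    seed: int | None = None,
    au_scales: tuple[float, ...] = AU_SCALES,
    au_replicates_per_scale: int = 10000,
) -> TopoTestResult:
    """All topology tests from a per-site log-likelihood matrix.

    Returns a table with one row per tree: delta log-likelihood from the
    best tree, bp-RELL, one-sided KH, SH, weighted KH/SH, c-ELW, and the
    AU p-value, plus ``in_ci_<test>`` flags at level 0.05.
    """
    rng = np.random.default_rng(seed)
    n_trees, n_sites = site_logl.shape
    totals = site_logl.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals.max() - totals

    rep = rell_matrix(site_logl, replicates=replicates, seed=int(rng.integers(2**31)))
    B = rep.shape[0]

    # bp-RELL: proportion of replicates in which each tree is best
    # (exact ties split fractionally)
    bp_rell = _best_fractions(rep).mean(axis=0)

    # c-ELW: mean normalized likelihood weight (log-space softmax per replicate)
    m = rep.max(axis=1, keepdims=True)
    w = np.exp(rep - m)
    c_elw = (w / w.sum(axis=1, keepdims=True)).mean(axis=0)

    p_kh = np.ones(n_trees)
    p_wkh = np.ones(n_trees)
    p_sh = np.ones(n_trees)
    p_wsh = np.ones(n_trees)

    # centered replicate totals (Shimodaira-Hasegawa centering)
    centered = rep - rep.mean(axis=0, keepdims=True)

    for i in range(n_trees):
        if i == best:
            continue
        # KH: one-sided test of tree i against the ML tree
        d_obs = totals[best] - totals[i]
        d_rep = centered[:, best] - centered[:, i]
        if np.allclose(d_rep, 0) and d_obs <= 0:
            p_kh[i] = 1.0
        else:
            p_kh[i] = float(np.mean(d_rep >= d_obs))
        sd = d_rep.std(ddof=1)
        if sd > 0:
            p_wkh[i] = float(np.mean(d_rep / sd >= d_obs / sd))
        else:
            p_wkh[i] = 1.0
    # the best tree's KH p compares it to the runner-up
    runner = int(np.argsort(-totals)[1]) if n_trees > 1 else best
    if n_trees > 1:
        d_obs = totals[best] - totals[runner]
        d_rep = centered[:, runner] - centered[:, best]
        p_kh[best] = float(np.mean(d_rep >= -d_obs)) if not np.allclose(d_rep, 0) else 1.0
        sd = d_rep.std(ddof=1)
        p_wkh[best] = (
            float(np.mean(d_rep / sd >= -d_obs / sd)) if sd > 0 else 1.0
        )

    # SH: max over the candidate set of centered differences
    rep_max = centered.max(axis=1)
    sds = np.empty(n_trees)
    for i in range(n_trees):
        d_obs = totals.max() - totals[i]
        stat_rep = rep_max - centered[:, i]
        p_sh[i] = float(np.mean(stat_rep >= d_obs))
        # WSH: studentized pairwise differences
        z_obs = -np.inf
        z_rep = np.full(B, -np.inf)
        for j in range(n_trees):
            if j == i:
                continue
            dr = centered[:, j] - centered[:, i]
            sd = dr.std(ddof=1)
            if sd <= 0:
                continue
            z_obs = max(z_obs, (totals[j] - totals[i]) / sd)
            z_rep = np.maximum(z_rep, dr / sd)
        if np.isfinite(z_obs):
            p_wsh[i] = float(np.mean(z_rep >= z_obs))
        else:
            p_wsh[i] = 1.0

    p_au = au_test(
        site_logl,
        scales=au_scales,
        replicates_per_scale=au_replicates_per_scale,
        seed=int(rng.integers(2**31)),
    )

    df = pd.DataFrame(
        {
            "delta_logl": delta,
            "bp_rell": bp_rell,
            "p_kh": p_kh,
            "p_sh": p_sh,
            "p_wkh": p_wkh,
            "p_wsh": p_wsh,
            "c_elw": c_elw,
            "p_au": p_au,
        }
    )
    for test in ("bp_rell", "p_kh", "p_sh", "p_wkh", "p_wsh", "c_elw", "p_au"):
        df[f"in_ci_{test}"] = df[test] >= 0.05
    return TopoTestResult(table=df)


def au_test(
    site_logl: np.ndarray,
    scales: tuple[float, ...] = AU_SCALES,
    replicates_per_scale: int = 10000,
    seed: int | None = None,
) -> np.ndarray:
    """Approximately unbiased test p-values by multiscale bootstrap.

    For each tree the bootstrap proportion of being best, bp(r), is taken
    at several resampling scales r; z(r) = Phi^-1(1 - bp(r)) is regressed
    on d*sqrt(r) + c/sqrt(r) by weighted least squares, and
    p_AU = 1 - Phi(d - c).  Degenerate proportions are clamped to
    (1/(2B), 1 - 1/(2B)); trees with fewer than two informative scales get
    p 0 or 1 according to their dominant bp.
    """
    rng = np.random.default_rng(seed)
    n_trees, n_sites = site_logl.shape
    B = replicates_per_scale
    scales_arr = np.asarray(scales, dtype=float)
    bp = np.empty((len(scales_arr), n_trees))
    for si, r in enumerate(scales_arr):
        rep = rell_matrix(
            site_logl, replicates=B, seed=int(rng.integers(2**31)), scale=r
        )
        bp[si] = _best_fractions(rep).mean(axis=0)
    lo, hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    p_au = np.empty(n_trees)
    for i in range(n_trees):
        informative = (bp[:, i] > 0) & (bp[:, i] < 1)
        if informative.sum() < 2:
            p_au[i] = 1.0 if bp[:, i].mean() > 0.5 else 0.0
            continue
        bpc = np.clip(bp[:, i], lo, hi)
        z = norm.ppf(1.0 - bpc)
        sq = np.sqrt(scales_arr)
        X = np.column_stack([sq, 1.0 / sq])
        # binomial variance weights on the probit scale
        var = bpc * (1 - bpc) / (B * norm.pdf(norm.ppf(bpc)) ** 2)
        W = 1.0 / var
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        d, c = beta
        p_au[i] = float(norm.sf(d - c))
    return p_au
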