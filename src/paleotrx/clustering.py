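"""Dimensionality reduction and fuzzy clustering of binary transcriptomes.

Two embeddings are provided: ordinary centered PCA on TPM values (a noisy
baseline) and logistic PCA on the binary encoding, which projects in the
Bernoulli natural-parameter space and is fitted by a
majorization-minimization scheme whose deviance is non-increasing per
iteration.  Soft structure is summarized by fuzzy C-means (FCM) with
Manhattan distance and a data-driven fuzzifier: the Schwämmle–Jensen
estimate

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

for N samples in D dimensions, which approaches 1 (near-hard clustering)
for high-dimensional data.  The number of clusters is surveyed over a K
range with the elbow criterion (largest second difference of the
objective) and sample re-partitioning counts between consecutive K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from paleotrx.data_io import MISSING, BinaryMatrix, ExpressionMatrix


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x dims
    variance_explained: np.ndarray | None
    method: str


@dataclass
class ClusterResult:
    """Fuzzy C-means output: soft memberships, centroids, objective trace."""

    sample_ids: list[str]
    K: int
    membership: np.ndarray  # samples x K, rows sum to 1
    centroids: np.ndarray  # K x genes
    fuzzifier: float
    objective_trace: list[float]
    distance: str

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.membership, axis=1)

    def membership_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.membership,
            index=self.sample_ids,
            columns=[f"cluster{k + 1}" for k in range(self.K)],
        )
        df["max_cluster"] = [f"cluster{k + 1}" for k in self.hard_labels]
        return df


# ---------------------------------------------------------------------------
# logistic PCA (Bernoulli natural-parameter projection)


def _bernoulli_deviance(X: np.ndarray, theta: np.ndarray) -> float:
    # -2 log-likelihood of X under logit parameters theta
    return float(2.0 * np.sum(np.logaddexp(0.0, theta) - X * theta))


def logistic_pca(
    bm: BinaryMatrix,
    k_dims: int = 4,
    m_approx: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    cv_grid: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> EmbeddingResult:
    """Logistic PCA of a binary matrix (no missing, no invariant columns).

    The model represents the natural parameters as a rank-``k_dims``
    projection of the scaled saturated model m_approx * (2X - 1):
    theta = mu + (thetaTilde - mu) U U'.  U is fitted by iterative
    majorization (each step solves a symmetric eigenproblem), which makes
    the Bernoulli deviance non-increasing.  When ``m_approx`` is not
    given it is chosen from ``cv_grid`` by row-wise cross-validated
    deviance.  Scores are the projections (thetaTilde - mu) U.
    """
    if (bm.states == MISSING).any():
        raise ValueError("logistic PCA requires a matrix without missing states")
    X = bm.states.astype(float)
    n, d = X.shape
    if k_dims < 2:
        raise ValueError("k_dims must be >= 2")
    if np.any(X.min(axis=0) == X.max(axis=0)):
        raise ValueError("invariant columns present; filter them first")

    if m_approx is None:
        m_approx = _select_m_approx(X, k_dims, cv_grid, cv_folds, seed)

    U, mu, dev_trace = _fit_lpca(X, k_dims, m_approx, max_iter, tol)
    theta_tilde = m_approx * (2.0 * X - 1.0)
    scores = (theta_tilde - mu) @ U
    # report the share of natural-parameter variance captured per dimension
    centered = theta_tilde - mu
    total = float(np.sum(centered**2))
    ve = np.sum((centered @ U) ** 2, axis=0) / total if total > 0 else None
    return EmbeddingResult(
        sample_ids=list(bm.taxa),
        scores=scores,
        variance_explained=ve,
        method="logistic_pca",
    )


def _fit_lpca(X, k, m_approx, max_iter, tol):
    n, d = X.shape
    theta_tilde = m_approx * (2.0 * X - 1.0)
    mu = theta_tilde.mean(axis=0)
    # initialize from ordinary PCA of the saturated parameters
    centered = theta_tilde - mu
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    U = Vt[:k].T
    dev_trace = []
    prev = np.inf
    for _ in range(max_iter):
        theta = mu + centered @ U @ U.T
        dev = _bernoulli_deviance(X, theta)
        dev_trace.append(dev)
        if prev - dev < tol:
            break
        prev = dev
        # majorization: quadratic upper bound with curvature 1/4
        Z = theta + 4.0 * (X - _sigmoid(theta))
        Zc = Z - mu
        M = centered.T @ Zc + Zc.T @ centered - centered.T @ centered
        M = 0.5 * (M + M.T)
        vals, vecs = np.linalg.eigh(M)
        U = vecs[:, np.argsort(vals)[::-1][:k]]
    return U, mu, dev_trace


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _select_m_approx(X, k, grid, folds, seed):
    """Row-held-out cross-validation of the saturated-model scale."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for i, idx in enumerate(perm):
        fold_of[idx] = i % folds
    best_m, best_dev = grid[0], np.inf
    for m_approx in grid:
        dev = 0.0
        for f in range(folds):
            train = X[fold_of != f]
            test = X[fold_of == f]
            if len(train) <= k or len(test) == 0:
                continue
            U, mu, _ = _fit_lpca(train, k, m_approx, max_iter=50, tol=1e-4)
            tt = m_approx * (2.0 * test - 1.0)
            theta = mu + (tt - mu) @ U @ U.T
            dev += _bernoulli_deviance(test, theta)
        if dev < best_dev:
            best_m, best_dev = m_approx, dev
    return best_m


# ---------------------------------------------------------------------------
# ordinary PCA baseline on TPMs


def pca_baseline(expr: ExpressionMatrix, k_dims: int = 4) -> EmbeddingResult:
    """Centered PCA of TPM values (genes with missing entries dropped)."""
    if expr.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    complete = ~np.isnan(expr.values).any(axis=1)
    X = expr.values[complete].T  # samples x genes
    k = min(k_dims, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    return EmbeddingResult(
        sample_ids=list(expr.sample_ids),
        scores=scores[:, :k],
        variance_explained=pca.explained_variance_ratio_,
        method="pca",
    )


# ---------------------------------------------------------------------------
# fuzzy C-means


def estimate_fuzzifier(n_samples: int, n_features: int) -> float:
    """Data-size-based fuzzifier estimate (Schwämmle–Jensen).

    Decreases toward 1 as dimensionality grows, giving near-hard
    memberships for transcriptome-scale feature counts.
    """
    if n_samples < 3 or n_features < 2:
        raise ValueError("need n_samples >= 3 and n_features >= 2")
    N, D = float(n_samples), float(n_features)
    return 1.0 + (1418.0 / N + 22.05) * D**-2 + (12.33 / N + 0.243) * D ** (
        -0.0406 * math.log(N) - 0.1134
    )


def _distances(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    if metric == "manhattan":
        return np.abs(X[:, None, :] - C[None, :, :]).sum(axis=2)
    if metric == "euclidean":
        return np.sqrt(((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    raise ValueError(f"unknown distance {metric!r}")


def fcm(
    data: np.ndarray,
    sample_ids: list[str],
    K: int,
    m: float,
    distance: str = "manhattan",
    seed: int | None = None,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> ClusterResult:
    """Fuzzy C-means with the standard Bezdek updates.

    Membership u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)); centroids are the
    u^m-weighted minimizers of the chosen distance — per-coordinate
    weighted medians for Manhattan, weighted means for Euclidean — so the
    objective J = sum u^m d is non-increasing per iteration.  The best of
    ``restarts`` random initializations (perturbed data rows) is returned.
    A sample at zero distance from a centroid receives full membership
    there; a centroid losing all mass is re-initialized from a random row.
    """
    X = np.asarray(data, dtype=float)
    n, d = X.shape
    if K < 2 or K > n:
        raise ValueError(f"K={K} out of range for {n} samples")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(max(1, restarts)):
        rows = rng.choice(n, size=K, replace=False)
        C = X[rows] + rng.normal(0, 0.01, size=(K, d))
        trace: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            D = _distances(X, C, distance)
            U = _memberships(D, m)
            J = float(np.sum(U**m * D))
            trace.append(J)
            Um = U**m
            mass = Um.sum(axis=0)
            dead = mass < 1e-12
            if dead.any():
                C[dead] = X[rng.choice(n, size=int(dead.sum()))]
                continue
            if distance == "manhattan":
                C = _weighted_median_centroids(X, Um)
            else:
                C = (Um.T @ X) / mass[:, None]
            if prev - J < tol:
                break
            prev = J
        res = ClusterResult(
            sample_ids=list(sample_ids),
            K=K,
            membership=U,
            centroids=C,
            fuzzifier=m,
            objective_trace=trace,
            distance=distance,
        )
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = res
    return best


def _weighted_median_centroids(X: np.ndarray, Um: np.ndarray) -> np.ndarray:
    """Per-coordinate weighted medians: the L1-optimal centroids."""
    n, d = X.shape
    K = Um.shape[1]
    order = np.argsort(X, axis=0)  # (n, d) per-column sort
    C = np.empty((K, d))
    for k in range(K):
        w_sorted = Um[:, k][order]  # (n, d)
        cum = np.cumsum(w_sorted, axis=0)
        half = 0.5 * cum[-1]
        pick = np.argmax(cum >= half, axis=0)
        C[k] = X[order[pick, np.arange(d)], np.arange(d)]
    return C


def _memberships(D: np.ndarray, m: float) -> np.ndarray:
    """Membership update; zero-distance samples get a hard assignment.

    Distances are scaled by each row's minimum before exponentiation so
    the nearest cluster's term is exactly 1 — with fuzzifiers near 1 the
    exponent is huge and unscaled powers would underflow to all-zero
    rows."""
    zero = D <= 1e-12
    safe = np.maximum(D, 1e-300)
    ratio = safe / safe.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        inv = ratio ** (-2.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
    hard = zero.any(axis=1)
    if hard.any():
        U[hard] = 0.0
        U[hard] = zero[hard] / zero[hard].sum(axis=1, keepdims=True)
    return U


def fcm_binary(
    bm: BinaryMatrix,
    K: int,
    m: float | None = None,
    distance: str = "manhattan",
    seed: int | None = None,
    restarts: int = 20,
) -> ClusterResult:
    """FCM on a filtered binary matrix (rows = taxa and/or ancestral nodes)."""
    if (bm.states == MISSING).any():
        raise ValueError("FCM requires a matrix without missing states; filter first")
    if m is None:
        m = estimate_fuzzifier(bm.n_taxa, bm.n_genes)
    return fcm(
        bm.states.astype(float), list(bm.taxa), K, m,
        distance=distance, seed=seed, restarts=restarts,
    )


def select_k(
    data: np.ndarray,
    sample_ids: list[str],
    k_range: range = range(2, 10),
    m: float = 1.05,
    distance: str = "manhattan",
    seed: int | None = None,
    restarts: int = 10,
) -> pd.DataFrame:
    """Survey cluster counts: objective per K, elbow statistic, stability.

    The elbow statistic is the second difference of the objective
    J(K-1) - 2 J(K) + J(K+1) (largest value = sharpest bend); stability
    counts how many samples change their maximum-membership cluster
    between consecutive K (best-matched by overlap).
    """
    ks = list(k_range)
    if not ks or ks[0] < 2 or ks[-1] >= len(sample_ids):
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    rng = np.random.default_rng(seed)
    results = {}
    for K in ks:
        results[K] = fcm(
            data, sample_ids, K, m, distance=distance,
            seed=int(rng.integers(2**31)), restarts=restarts,
        )
    rows = []
    prev_labels = None
    obj = {K: results[K].objective_trace[-1] for K in ks}
    for K in ks:
        elbow = np.nan
        if K - 1 in obj and K + 1 in obj:
            elbow = obj[K - 1] - 2 * obj[K] + obj[K + 1]
        labels = results[K].hard_labels
        reassigned = np.nan
        if prev_labels is not None:
            reassigned = _count_reassigned(prev_labels, labels)
        rows.append(
            {"K": K, "objective": obj[K], "elbow": elbow, "reassigned": reassigned}
        )
        prev_labels = labels
    return pd.DataFrame(rows)


def _count_reassigned(prev: np.ndarray, cur: np.ndarray) -> int:
    """Samples whose cluster at K does not descend from their cluster at
    K-1 under the best overlap matching (clustree-style)."""
    moved = 0
    for c in np.unique(cur):
        members = cur == c
        # dominant parent cluster of this cluster
        parent = np.bincount(prev[members]).argmax()
        moved += int(np.sum(prev[members] != parent))
    return moved


def adjusted_rand_index(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))
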