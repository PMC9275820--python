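"""Logistic PCA, PCA baseline, fuzzifier estimation, FCM, K selection."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from paleotrx.clustering import (
    estimate_fuzzifier,
    fcm,
    fcm_binary,
    logistic_pca,
    pca_baseline,
    select_k,
)
from paleotrx.data_io import BinaryMatrix, ExpressionMatrix, filter_columns


def block_matrix(rng, n_per=10, d_per=20, blocks=2, flip=0.05):
    n, d = n_per * blocks, d_per * blocks
    X = np.zeros((n, d))
    for b in range(blocks):
        X[b * n_per : (b + 1) * n_per, b * d_per : (b + 1) * d_per] = 1
    noise = rng.random(X.shape) < flip
    return np.abs(X - noise)


class TestLogisticPca:
    @pytest.fixture
    def blocks_bm(self, rng):
        X = block_matrix(rng).astype(np.int8)
        bm = BinaryMatrix(
            taxa=[f"s{i}" for i in range(X.shape[0])],
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            states=X,
        )
        filt, _ = filter_columns(bm)
        return filt

    def test_duplicated_rows_identical_scores(self, blocks_bm):
        emb = logistic_pca(blocks_bm, k_dims=2, m_approx=5.0)
        # rows 0..9 are near-duplicates up to flip noise; exact duplicates:
        states = blocks_bm.states.copy()
        states[1] = states[0]
        bm = BinaryMatrix(taxa=blocks_bm.taxa, gene_ids=blocks_bm.gene_ids, states=states)
        emb2 = logistic_pca(bm, k_dims=2, m_approx=5.0)
        assert np.allclose(emb2.scores[0], emb2.scores[1], atol=1e-10)

    def test_blocks_separate_on_first_dimension(self, blocks_bm):
        emb = logistic_pca(blocks_bm, k_dims=2, m_approx=5.0)
        a, b = emb.scores[:10, 0], emb.scores[10:, 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_deviance_monotone(self, blocks_bm):
        from paleotrx.clustering import _bernoulli_deviance, _fit_lpca

        X = blocks_bm.states.astype(float)
        _, _, trace = _fit_lpca(X, 2, 5.0, max_iter=100, tol=1e-9)
        diffs = np.diff(trace)
        assert (diffs <= 1e-8).all()

    def test_rejects_missing_and_invariant(self, rng):
        from paleotrx.data_io import MISSING

        bad = BinaryMatrix(
            taxa=["a", "b", "c"],
            gene_ids=["g1", "g2"],
            states=np.array([[0, 1], [1, MISSING], [0, 1]], dtype=np.int8),
        )
        with pytest.raises(ValueError):
            logistic_pca(bad, k_dims=2)


class TestPcaBaseline:
    def test_variance_explained_sums_to_one(self, rng):
        em = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(40)],
            sample_ids=[f"s{j}" for j in range(8)],
            values=rng.lognormal(1, 1, size=(40, 8)),
        )
        emb = pca_baseline(em)
        assert emb.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_sample_identical_scores(self, rng):
        vals = rng.lognormal(1, 1, size=(30, 6))
        vals[:, 1] = vals[:, 0]
        em = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(30)],
            sample_ids=[f"s{j}" for j in range(6)],
            values=vals,
        )
        emb = pca_baseline(em)
        assert np.allclose(emb.scores[0], emb.scores[1], atol=1e-9)

    def test_isotropic_noise_flat_scree(self, rng):
        em = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(2000)],
            sample_ids=[f"s{j}" for j in range(20)],
            values=rng.normal(10, 1, size=(2000, 20)).clip(0),
        )
        ve = pca_baseline(em).variance_explained
        assert ve.max() < 2 * ve.mean()


class TestEstimateFuzzifier:
    def test_direct_formula(self):
        N, D = 50, 10000
        expected = (
            1.0
            + (1418.0 / N + 22.05) * D**-2
            + (12.33 / N + 0.243) * D ** (-0.0406 * math.log(N) - 0.1134)
        )
        assert estimate_fuzzifier(N, D) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_dimension(self):
        assert estimate_fuzzifier(50, 100) > estimate_fuzzifier(50, 10000)

    def test_approaches_one_for_huge_dimension(self):
        assert 1.0 < estimate_fuzzifier(23, 10**9) < estimate_fuzzifier(23, 10**5) < 1.1

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            estimate_fuzzifier(2, 100)


class TestFcm:
    def test_equidistant_point_half_membership(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        res = fcm(X, ["a", "b", "mid"], K=2, m=2.0, seed=1, restarts=10)
        assert np.allclose(res.membership[2], [0.5, 0.5], atol=1e-6)

    def test_near_one_fuzzifier_hardens(self, rng):
        X = block_matrix(rng)
        res = fcm(X, [f"s{i}" for i in range(20)], K=2, m=1.01, seed=0, restarts=5)
        assert res.membership.max(axis=1).min() > 0.99

    def test_block_recovery(self, rng):
        X = block_matrix(rng)
        res = fcm(X, [f"s{i}" for i in range(20)], K=2, m=1.2, seed=0, restarts=10)
        ari = adjusted_rand_score([0] * 10 + [1] * 10, res.hard_labels)
        assert ari == 1.0

    def test_invariants(self, rng):
        X = block_matrix(rng, blocks=3)
        res = fcm(X, [f"s{i}" for i in range(30)], K=3, m=1.3, seed=2, restarts=5)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-12)
        trace = res.objective_trace
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))
        # fixed point: rerunning from the solution barely moves the objective
        res2 = fcm(X, [f"s{i}" for i in range(30)], K=3, m=1.3, seed=3, restarts=5)
        assert res2.objective_trace[-1] == pytest.approx(trace[-1], rel=0.05)

    def test_validation(self, rng):
        X = block_matrix(rng)
        with pytest.raises(ValueError):
            fcm(X, [f"s{i}" for i in range(20)], K=1, m=1.2)
        with pytest.raises(ValueError):
            fcm(X, [f"s{i}" for i in range(20)], K=2, m=1.0)

    def test_fcm_binary_rejects_missing(self):
        from paleotrx.data_io import MISSING

        bm = BinaryMatrix(
            taxa=["a", "b", "c"],
            gene_ids=["g1", "g2"],
            states=np.array([[0, 1], [1, MISSING], [0, 1]], dtype=np.int8),
        )
        with pytest.raises(ValueError):
            fcm_binary(bm, K=2)


class TestSelectK:
    def test_elbow_at_planted_k(self, rng):
        X = block_matrix(rng, n_per=10, d_per=20, blocks=3, flip=0.03)
        table = select_k(X, [f"s{i}" for i in range(30)], range(2, 7), m=1.2, seed=0, restarts=5)
        best = int(table.loc[table.elbow.idxmax(), "K"])
        assert best == 3

    def test_objective_non_increasing_in_k(self, rng):
        X = block_matrix(rng, blocks=2)
        table = select_k(X, [f"s{i}" for i in range(20)], range(2, 6), m=1.2, seed=1, restarts=5)
        obj = table.objective.to_numpy()
        assert (np.diff(obj) <= 1e-6).all()

    def test_k_equals_samples_zero_objective(self, rng):
        X = block_matrix(rng, n_per=3, d_per=5, blocks=2)
        res = fcm(X, [f"s{i}" for i in range(6)], K=6, m=1.2, seed=0, restarts=5)
        assert res.objective_trace[-1] == pytest.approx(0.0, abs=1e-6)

    def test_range_validation(self, rng):
        X = block_matrix(rng)
        with pytest.raises(ValueError):
            select_k(X, [f"s{i}" for i in range(20)], range(2, 40), m=1.2)
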