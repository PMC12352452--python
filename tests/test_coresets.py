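"""Kernel bundles, discrepancy, NNLS weights, norm sampling, kernel herding.

The brute-force oracles here materialize the quadratic-form embeddings
explicitly (each row x becomes the vector vec(x^T x)), which is feasible only
for a handful of columns — exactly the regime where the kernelized
implementation must agree with it.
"""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import nnls as scipy_nnls

from tensorcoresets.coresets import (
    build_kernel_bundle,
    discrepancy,
    nnls_weights,
    norm_rescaled_weights,
    norm_sample,
    wkh_select,
)


def explicit_embeddings(X):
    """All rows' embeddings as columns of a (cols^2 x rows) matrix."""
    return np.stack([np.outer(x, x).ravel() for x in X], axis=1)


def projected_gradient_nnls(K, c, iters=20000, tol=1e-12):
    """Independent minimizer of w^T K w - 2 w^T c over w >= 0."""
    L = np.linalg.eigvalsh(K).max() * 2.0
    w = np.zeros(len(c))
    for _ in range(iters):
        grad = 2.0 * (K @ w - c)
        w_new = np.clip(w - grad / L, 0.0, None)
        if np.linalg.norm(w_new - w) < tol * max(1.0, np.linalg.norm(w)):
            w = w_new
            break
        w = w_new
    return w


class TestKernelBundle:
    def test_kernels_match_explicit_embeddings(self, rng):
        X = rng.standard_normal((4, 3))
        idx = [0, 2]
        bundle = build_kernel_bundle(X, idx)
        A = explicit_embeddings(X)
        b = A.sum(axis=1)
        assert np.allclose(bundle.K, A[:, idx].T @ A[:, idx], rtol=1e-10)
        assert np.allclose(bundle.c, A[:, idx].T @ b, rtol=1e-10)
        assert np.isclose(bundle.full_embedding_normsq, b @ b, rtol=1e-10)

    def test_full_subset_gives_full_gram(self, rng):
        X = rng.standard_normal((5, 3))
        bundle = build_kernel_bundle(X, np.arange(5))
        assert np.allclose(bundle.P, X @ X.T)
        assert np.allclose(bundle.P_II, X @ X.T)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            build_kernel_bundle(rng.standard_normal((4, 3)), [])


class TestDiscrepancy:
    def test_full_subset_unit_weights_zero(self, rng):
        X = rng.standard_normal((5, 3))
        bundle = build_kernel_bundle(X, np.arange(5))
        assert discrepancy(bundle, np.ones(5)) == 0.0

    def test_zero_weights_give_full_embedding_norm(self, rng):
        X = rng.standard_normal((5, 3))
        bundle = build_kernel_bundle(X, [1, 3])
        assert np.isclose(
            discrepancy(bundle, np.zeros(2)),
            np.linalg.norm(X.T @ X, "fro") ** 2,
            rtol=1e-10,
        )

    def test_matches_quadratic_form_oracle(self, rng):
        X = rng.standard_normal((5, 3))
        idx = [0, 2, 4]
        w = rng.uniform(0.1, 3.0, size=3)
        bundle = build_kernel_bundle(X, idx)
        target = X.T @ X
        approx = sum(wi * np.outer(X[i], X[i]) for wi, i in zip(w, idx))
        oracle = np.linalg.norm(approx - target, "fro") ** 2
        assert np.isclose(discrepancy(bundle, w), oracle, rtol=1e-10)

    def test_missing_norm_raises(self, rng):
        X = rng.standard_normal((4, 3))
        bundle = build_kernel_bundle(X, [0, 1], with_full_normsq=False)
        with pytest.raises(ValueError):
            discrepancy(bundle, np.ones(2))


class TestNnlsWeights:
    def test_full_subset_recovers_unit_weights(self, rng):
        X = rng.standard_normal((5, 3))
        bundle = build_kernel_bundle(X, np.arange(5))
        w = nnls_weights(bundle)
        assert np.allclose(w, np.ones(5), atol=1e-6)
        assert discrepancy(bundle, w) <= 1e-8

    def test_duplicated_row_gets_weight_two(self):
        X = np.zeros((4, 3))
        X[0] = X[2] = [1.0, -2.0, 0.5]
        bundle = build_kernel_bundle(X, [0])
        assert np.allclose(nnls_weights(bundle), [2.0], atol=1e-10)

    def test_matches_projected_gradient_oracle(self, rng):
        for _ in range(10):
            X = rng.standard_normal((6, 3))
            idx = rng.choice(6, size=2, replace=False)
            bundle = build_kernel_bundle(X, idx)
            w = nnls_weights(bundle)
            w_oracle = projected_gradient_nnls(bundle.K, bundle.c)
            assert np.allclose(w, w_oracle, atol=1e-6)

    def test_kkt_conditions(self, rng):
        scale_tol = 1e-8
        for _ in range(20):
            X = rng.standard_normal((8, 4))
            idx = rng.choice(8, size=4, replace=False)
            bundle = build_kernel_bundle(X, idx)
            w = nnls_weights(bundle)
            grad = 2.0 * (bundle.K @ w - bundle.c)
            tol = scale_tol * max(1.0, np.abs(bundle.c).max())
            assert np.all(grad[w == 0] >= -tol)
            assert np.all(np.abs(grad[w > 0]) <= tol)

    def test_beats_unit_and_norm_rescaled_weights(self, rng):
        for _ in range(20):
            X = rng.standard_normal((10, 4))
            idx = norm_sample(X, 3, rng)
            bundle = build_kernel_bundle(X, idx)
            d_opt = discrepancy(bundle, nnls_weights(bundle))
            assert d_opt <= discrepancy(bundle, np.ones(3)) * (1 + 1e-10)
            d_eq4 = discrepancy(bundle, norm_rescaled_weights(X, idx))
            assert d_opt <= d_eq4 * (1 + 1e-10)


class TestNormSample:
    def test_single_nonzero_row_certain(self):
        X = np.zeros((3, 2))
        X[1] = [1.0, 1.0]
        for seed in range(5):
            assert norm_sample(X, 1, seed)[0] == 1

    def test_indices_distinct_and_zero_rows_excluded(self, rng):
        X = rng.standard_normal((8, 3))
        X[4] = 0.0
        idx = norm_sample(X, 7, rng)
        assert len(set(idx.tolist())) == 7
        assert 4 not in idx

    def test_size_exceeding_nonzero_rows_rejected(self):
        X = np.zeros((3, 2))
        X[0] = [1.0, 0.0]
        with pytest.raises(ValueError):
            norm_sample(X, 2, 0)

    def test_first_draw_frequencies_proportional_to_squared_norm(self):
        X = np.array([[2.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        rng = np.random.default_rng(11)
        draws = np.array([norm_sample(X, 1, rng)[0] for _ in range(10_000)])
        counts = np.bincount(draws, minlength=3)
        assert counts[2] == 0
        chi2 = stats.chisquare(counts[:2], f_exp=[8000, 2000]).pvalue
        assert chi2 > 0.001


class TestWkhSelect:
    def test_identical_rows_single_pick(self):
        X = np.tile([1.0, -1.0, 2.0], (5, 1))
        cs = wkh_select(X @ X.T, 1)
        assert cs.indices.tolist() == [0]  # tie-break: smallest index
        assert np.isclose(cs.weights[0], 5.0, atol=1e-8)
        assert cs.discrepancy_value <= 1e-6

    def test_full_size_reaches_zero_discrepancy(self, rng):
        X = rng.standard_normal((5, 5))
        cs = wkh_select(X @ X.T, 5)
        assert cs.discrepancy_value <= 1e-6 * np.linalg.norm(X.T @ X) ** 2

    def test_trace_matches_explicit_embedding_greedy_oracle(self, rng):
        X = rng.standard_normal((6, 3))
        A = explicit_embeddings(X)  # 9 x 6
        b = A.sum(axis=1)
        norms = np.linalg.norm(A, axis=0)
        sel, w = [], np.empty(0)
        oracle_trace = []
        for _ in range(4):
            resid = b - (A[:, sel] @ w if sel else 0.0)
            score = (A.T @ resid) / norms
            score[sel] = -np.inf
            i = int(np.argmax(score))
            sel.append(i)
            w, _ = scipy_nnls(A[:, sel], b)
            oracle_trace.append(np.linalg.norm(A[:, sel] @ w - b) ** 2)
        cs = wkh_select(X @ X.T, 4)
        assert cs.indices[:4].tolist() == sel
        assert np.allclose(cs.trace, oracle_trace, rtol=1e-6, atol=1e-8)
        assert np.allclose(cs.weights, w, atol=1e-6)

    def test_discrepancy_sequence_nonincreasing(self, rng):
        for _ in range(100):
            X = rng.standard_normal((7, 4))
            cs = wkh_select(X @ X.T, 5)
            diffs = np.diff(cs.trace)
            assert np.all(diffs <= 1e-8 * max(1.0, cs.trace[0]))

    def test_zero_rows_skipped_and_size_checked(self):
        X = np.zeros((4, 2))
        X[0] = [1.0, 0.0]
        X[1] = [0.0, 2.0]
        cs = wkh_select(X @ X.T, 2)
        assert set(cs.indices.tolist()) == {0, 1}
        with pytest.raises(ValueError):
            wkh_select(X @ X.T, 3)
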