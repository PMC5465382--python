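"""Dense PCA, the sparse solver, deflation and variance accounting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moodlatent import (
    DensePCA,
    SparsePCA,
    adjusted_variance,
    cardinality_path,
    covariance,
    deflate,
    pca,
    sparse_component,
    spca_fit,
)
from moodlatent.exceptions import InsufficientDataError, ValidationError
from tests.conftest import random_psd


def brute_force_best_subset(S, k):
    """Independent oracle: leading eigenvalue over all k-item submatrices."""
    M = S.shape[0]
    best = -np.inf
    for idx in itertools.combinations(range(M), k):
        vals = np.linalg.eigvalsh(S[np.ix_(idx, idx)])
        best = max(best, vals[-1])
    return best


class TestCovariance:
    def test_identical_rows_give_zero(self):
        assert np.allclose(covariance(np.zeros((2, 3))), 0.0)

    def test_hand_computed_example(self):
        t = np.array([-1.0, 0.0, 1.0])
        X = np.column_stack([t, 2 * t])
        assert np.allclose(covariance(X), [[1.0, 2.0], [2.0, 4.0]])

    def test_matches_two_pass_oracle(self, rng):
        X = rng.standard_normal((50, 4))
        # Independent two-pass computation.
        mean = [sum(X[:, j]) / 50 for j in range(4)]
        S = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                S[i, j] = sum(
                    (X[n, i] - mean[i]) * (X[n, j] - mean[j]) for n in range(50)
                ) / 49
        assert np.allclose(covariance(X), S, atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            covariance(np.ones((1, 3)))


class TestDensePCA:
    def test_diagonal_covariance(self, rng):
        # Columns with variances 2 and 1.
        X = rng.standard_normal((4000, 2)) * np.sqrt([2.0, 1.0])
        X -= X.mean(axis=0)
        fit = pca(X, n_components=2)
        assert abs(abs(fit.loadings[0, 0]) - 1.0) < 0.05
        assert fit.loadings[0, np.argmax(np.abs(fit.loadings[0]))] > 0
        assert fit.cum_variance_pct[-1] == pytest.approx(100.0)

    def test_eigenvalues_match_characteristic_polynomial(self, rng):
        X = rng.standard_normal((200, 6))
        S = covariance(X)
        est = DensePCA(n_components=6).fit(X)
        roots = np.sort(np.roots(np.poly(S)).real)[::-1]
        assert np.allclose(est.explained_variance_, roots, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        X = rng.standard_normal((100, 5))
        est = DensePCA(n_components=5).fit(X)
        G = est.components_ @ est.components_.T
        assert np.allclose(G, np.eye(5), atol=1e-8)

    def test_isotropic_shares_variance_equally(self):
        # Data whose covariance is isotropic (a multiple of the identity).
        X = np.vstack([np.eye(4), -np.eye(4)])
        fit = pca(X, n_components=4)
        increments = np.diff(np.concatenate([[0.0], fit.cum_variance_pct]))
        assert np.allclose(increments, 25.0)

    def test_transform_equals_projection(self, rng):
        X = rng.standard_normal((50, 4))
        est = DensePCA(n_components=2).fit(X)
        assert np.allclose(est.transform(X), X @ est.components_.T)


class TestSparseComponent:
    def test_dominant_diagonal_k1(self):
        S = np.diag([3.0, 2.0, 1.0])
        w, support, var = sparse_component(S, 1)
        assert np.allclose(w, [1, 0, 0])
        assert var == pytest.approx(3.0)

    def test_full_cardinality_pads_support(self):
        S = np.diag([3.0, 2.0, 1.0])
        w, support, var = sparse_component(S, 3)
        assert np.allclose(w, [1, 0, 0])
        assert support == (0, 1, 2)      # padded to k despite zero weights
        assert var == pytest.approx(3.0)

    def test_matches_exhaustive_oracle_k2(self, rng):
        S = random_psd(rng, 5)
        _, _, var = sparse_component(S, 2)
        assert var == pytest.approx(brute_force_best_subset(S, 2), abs=1e-6)

    def test_achieved_variance_at_least_best_single_item(self, rng):
        for _ in range(20):
            S = random_psd(rng, 6)
            for k in (1, 2, 3):
                _, _, var = sparse_component(S, k)
                assert var >= np.max(np.diag(S)) - 1e-10

    def test_invalid_inputs(self, rng):
        S = random_psd(rng, 4)
        with pytest.raises(ValidationError):
            sparse_component(S, 0)
        with pytest.raises(ValidationError):
            sparse_component(S, 5)
        with pytest.raises(ValidationError):
            sparse_component(rng.standard_normal((4, 4)), 2)

    def test_l1_solver_agrees_with_oracle(self, rng):
        """The penalized variant, bisected to the target cardinality,
        reaches the same optimum on small problems."""
        for _ in range(10):
            S = random_psd(rng, 5)
            for k in (1, 2, 3):
                _, _, var = sparse_component(S, k, solver="l1")
                assert var == pytest.approx(
                    brute_force_best_subset(S, k), abs=1e-6
                )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 5))
    def test_variance_bounded_by_dense_eigenvalue(self, seed, k):
        S = random_psd(np.random.default_rng(seed), 5)
        _, _, var = sparse_component(S, k)
        assert var <= np.linalg.eigvalsh(S)[-1] + 1e-8


class TestDeflate:
    def test_rank_one_matrix_annihilated(self):
        w = np.array([3.0, 4.0]) / 5.0
        X = np.outer([1.0, -2.0, 0.5], w)
        assert np.abs(deflate(X, w)).max() < 1e-12

    def test_orthogonal_direction_unchanged(self, rng):
        X = rng.standard_normal((30, 3))
        w = np.array([1.0, 0.0, 0.0])
        X[:, 0] = 0.0
        assert np.allclose(deflate(X, w), X)

    def test_zero_variance_along_direction(self, rng):
        X = rng.standard_normal((40, 5))
        w = rng.standard_normal(5)
        w /= np.linalg.norm(w)
        D = deflate(X, w)
        assert np.var(D @ w) < 1e-10

    def test_non_unit_vector_rejected(self, rng):
        with pytest.raises(ValidationError):
            deflate(rng.standard_normal((10, 3)), np.array([1.0, 1.0, 0.0]))


def planted_block_data(rng, n=2000, sds=(1.5, 1.2, 0.9), noise=0.3):
    """Three mutually exclusive 2-item blocks with decreasing variance."""
    supports = [(0, 1), (2, 3), (4, 5)]
    W = np.zeros((6, 3))
    for k, idx in enumerate(supports):
        W[list(idx), k] = 1 / np.sqrt(2)
    Z = rng.standard_normal((n, 3)) * np.asarray(sds)
    X = Z @ W.T + noise * rng.standard_normal((n, 6))
    return X - X.mean(axis=0), supports


class TestSpcaFit:
    def test_recovers_planted_blocks_in_order(self, rng):
        X, supports = planted_block_data(rng)
        fit = spca_fit(X, n_components=3, cardinality=2)
        assert [tuple(s) for s in fit.supports] == supports

    def test_full_cardinality_equals_dense_pca(self, rng):
        X = rng.standard_normal((200, 5))
        sparse = spca_fit(X, n_components=3, cardinality=5)
        dense = pca(X, n_components=3)
        for ws, wd in zip(sparse.loadings, dense.loadings):
            assert abs(abs(ws @ wd) - 1.0) < 1e-6

    def test_single_component_equals_sparse_component(self, rng):
        X = rng.standard_normal((100, 4))
        fit = spca_fit(X, n_components=1, cardinality=2)
        w, support, _ = sparse_component(covariance(X), 2)
        assert np.allclose(fit.loadings[0], w)
        assert fit.supports[0] == support

    def test_supports_have_configured_cardinality(self, rng):
        X = rng.standard_normal((100, 6))
        fit = spca_fit(X, n_components=3, cardinality=(1, 2, 3))
        assert [len(s) for s in fit.supports] == [1, 2, 3]

    def test_loadings_unit_norm(self, mz_centered):
        fit = spca_fit(mz_centered, n_components=3, cardinality=2)
        assert np.allclose(np.linalg.norm(fit.loadings, axis=1), 1.0,
                           atol=1e-10)

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((150, 6))
        a = spca_fit(X, n_components=3, cardinality=2, random_state=7)
        b = spca_fit(X, n_components=3, cardinality=2, random_state=7)
        assert np.array_equal(a.loadings, b.loadings)

    def test_sign_rule_largest_entry_positive(self, rng):
        X = rng.standard_normal((150, 6))
        fit = spca_fit(X, n_components=3, cardinality=2)
        for w in fit.loadings:
            assert w[np.argmax(np.abs(w))] > 0

    def test_auto_cardinality_reaches_variance_fraction(self, rng):
        X, _ = planted_block_data(rng)
        est = SparsePCA(
            n_components=1, cardinality="auto", auto_variance_fraction=0.9
        ).fit(X)
        dense_lead = np.linalg.eigvalsh(covariance(X))[-1]
        assert est.explained_variance_[0] >= 0.9 * dense_lead
        assert est.cardinalities_[0] <= 3


class TestAdjustedVariance:
    def test_dense_loadings_reduce_to_eigenvalue_ratios(self, rng):
        X = rng.standard_normal((300, 4))
        est = DensePCA(n_components=4).fit(X)
        adj = adjusted_variance(X, est.components_)
        assert np.allclose(adj, est.cum_variance_pct_, atol=1e-8)

    def test_duplicated_loading_adds_nothing(self, rng):
        X = rng.standard_normal((100, 3))
        w = np.array([1.0, 0.0, 0.0])
        adj = adjusted_variance(X, np.vstack([w, w]))
        assert adj[1] == pytest.approx(adj[0], abs=1e-10)

    def test_sparse_cumulative_dominated_by_dense(self, mz_centered):
        sparse = spca_fit(mz_centered, n_components=3, cardinality=2)
        dense = pca(mz_centered, n_components=3)
        assert np.all(np.diff(sparse.cum_variance_pct) >= -1e-10)
        assert np.all(
            sparse.cum_variance_pct <= dense.cum_variance_pct + 1e-8
        )
        assert sparse.cum_variance_pct[-1] <= 100.0 + 1e-8


class TestCardinalityPath:
    def test_k1_value_on_diagonal_matrix(self, rng):
        # Independent columns with variances ~3, 2, 1.
        X = rng.standard_normal((5000, 3)) * np.sqrt([3.0, 2.0, 1.0])
        path = cardinality_path(X, 0)
        total = np.trace(covariance(X))
        k1 = dict(path)[1]
        assert k1 == pytest.approx(100 * np.var(X[:, 0], ddof=1) / total,
                                   rel=1e-6)

    def test_monotone_and_dense_at_full_k(self, rng):
        for _ in range(5):
            X = rng.standard_normal((80, 5))
            path = cardinality_path(X, 0)
            values = [v for _, v in path]
            assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
            dense_pct = (
                100 * np.linalg.eigvalsh(covariance(X))[-1]
                / np.trace(covariance(X))
            )
            assert values[-1] == pytest.approx(dense_pct, abs=1e-8)

    def test_later_stage_path_uses_deflated_data(self, rng):
        X, _ = planted_block_data(rng)
        path0 = dict(cardinality_path(X, 0))
        path1 = dict(cardinality_path(X, 1))
        # After removing the strongest block, less variance is available.
        assert path1[2] < path0[2]
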