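import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from connage.plsr import (
    loo_rmsep,
    nipals_fit,
    repeated_splits,
    residualize,
    scrambled_null,
    select_ncomponents,
    split_sizes,
    variance_accounting,
)


def krylov_pls_predict(X, y, k, X_new):
    """Independent PLS1 oracle: k-component PLS prediction equals least
    squares restricted to the Krylov subspace span{s, As, ..., A^(k-1)s} with
    s = X'y and A = X'X (orthonormalized for numerical stability)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    s = Xc.T @ yc
    A = Xc.T @ Xc
    basis = [s]
    for _ in range(k - 1):
        basis.append(A @ basis[-1])
    Q, _ = np.linalg.qr(np.column_stack(basis))
    Z = Xc @ Q
    beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    return y.mean() + (X_new - X.mean(axis=0)) @ (Q @ beta)


class TestResidualize:
    def _covs(self, rng, n):
        return np.column_stack([rng.integers(0, 2, n), rng.normal(10, 2, n)])

    def test_orthogonal_predictor_unchanged(self, rng):
        n = 200
        covs = self._covs(rng, n)
        design = np.column_stack([np.ones(n), covs])
        x = rng.standard_normal(n)
        x -= design @ np.linalg.lstsq(design, x, rcond=None)[0]  # orthogonalize
        out = residualize(x[:, None], covs)
        assert np.allclose(out[:, 0], x, atol=1e-10)

    def test_exact_covariate_function_residual_zero(self, rng):
        covs = self._covs(rng, 100)
        x = 3.0 * covs[:, 1] - 7.0
        out = residualize(x[:, None], covs)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_matches_hat_matrix_oracle(self, rng):
        covs = self._covs(rng, 80)
        X = rng.standard_normal((80, 12))
        design = np.column_stack([np.ones(80), covs])
        hat = design @ np.linalg.inv(design.T @ design) @ design.T
        expected = X - hat @ X
        assert np.allclose(residualize(X, covs), expected, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        covs = np.column_stack([np.ones(50), np.ones(50) * 2])  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.standard_normal((50, 3)), covs)

    def test_dataframe_round_trip(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        out = residualize(X, self._covs(rng, 30))
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == list("abcd")


class TestNipals:
    def test_single_predictor_response_perfect_fit(self, rng):
        # orthogonal predictors: the first weight vector is exactly the
        # responding column, so one component reproduces y
        raw = rng.standard_normal((40, 6))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthonormal columns
        y = X[:, 2].copy()
        model = nipals_fit(X, y, 1)
        assert np.allclose(model.predict(X), y, atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.standard_normal((50, 30))
        y = rng.standard_normal(50)
        model = nipals_fit(X, y, 30)
        design = np.column_stack([np.ones(50), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(model.predict(X), design @ beta, atol=1e-8)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_matches_krylov_subspace_oracle(self, rng, k):
        X = rng.standard_normal((50, 30))
        y = X @ rng.standard_normal(30) * 0.3 + rng.standard_normal(50)
        X_new = rng.standard_normal((20, 30))
        model = nipals_fit(X, y, k)
        expected = krylov_pls_predict(X, y, k, X_new)
        assert np.allclose(model.predict(X_new, k), expected, atol=1e-8)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_sklearn_pls(self, rng, k):
        X = rng.standard_normal((50, 30))
        y = rng.standard_normal(50)
        model = nipals_fit(X, y, k)
        sk = PLSRegression(n_components=k, scale=False).fit(X, y)
        assert np.allclose(model.predict(X, k), sk.predict(X).ravel(), atol=1e-8)

    def test_score_orthogonality(self, rng):
        X = rng.standard_normal((60, 40))
        y = rng.standard_normal(60)
        T = nipals_fit(X, y, 8).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) <= 1e-8 * np.max(np.diag(gram))

    def test_prediction_invariant_to_column_order_and_sign_flips(self, rng):
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        model = nipals_fit(X, y, 3)
        base = model.predict(X)
        perm = rng.permutation(10)
        permuted = nipals_fit(X[:, perm], y, 3)
        assert np.allclose(permuted.predict(X[:, perm]), base, atol=1e-10)
        model.flip_component(1)
        assert np.allclose(model.predict(X), base, atol=1e-12)

    def test_degenerate_response_raises(self, rng):
        X = rng.standard_normal((30, 5))
        with pytest.raises(ValueError, match="component 1"):
            nipals_fit(X, np.full(30, 2.0), 1)


class TestLooRmsep:
    def test_constant_response_zero_error(self, rng):
        X = rng.standard_normal((20, 4))
        cv = loo_rmsep(X, np.full(20, 5.0), max_components=2)
        assert cv.rmsep[0] == pytest.approx(0.0)

    def test_matches_per_fold_refit_oracle(self, rng):
        """Brute-force oracle: one independent (sklearn) refit per left-out
        subject per depth."""
        X = rng.standard_normal((30, 8))
        y = X @ rng.standard_normal(8) * 0.5 + rng.standard_normal(30)
        K = 3
        cv = loo_rmsep(X, y, max_components=K)
        press = np.zeros((30, K))
        for i in range(30):
            keep = np.arange(30) != i
            for k in range(1, K + 1):
                sk = PLSRegression(n_components=k, scale=False).fit(X[keep], y[keep])
                press[i, k - 1] = (y[i] - sk.predict(X[i : i + 1]).item()) ** 2
        assert np.allclose(cv.press[:, 1:], press, atol=1e-8)
        assert np.allclose(cv.rmsep[1:], np.sqrt(press.mean(axis=0)), atol=1e-8)

    def test_pure_noise_rmsep_grows_with_depth_in_expectation(self):
        curves = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 10))
            y = rng.standard_normal(40)
            curves.append(loo_rmsep(X, y, max_components=4).rmsep)
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve[1:]) > -0.02)  # non-decreasing beyond 0

    def test_explained_variance_monotone_on_training_data(self, rng):
        X = rng.standard_normal((50, 20))
        y = X @ rng.standard_normal(20) + rng.standard_normal(50)
        cv = loo_rmsep(X, y, max_components=6)
        assert np.all(np.diff(cv.y_variance_pct) >= -1e-10)
        assert np.all(np.diff(cv.x_variance_pct) >= -1e-10)


class TestSelection:
    def test_recovers_two_planted_components(self):
        from connage.synthetic import simulate_feature_cohort

        hits = 0
        for seed in range(5):
            cohort = simulate_feature_cohort(150, n_nodes=20, seed=seed)
            cv = loo_rmsep(cohort.X.to_numpy(), cohort.age, max_components=6)
            hits += select_ncomponents(cv, rng=np.random.default_rng(seed)) == 2
        assert hits >= 4

    def test_independent_response_selects_zero(self):
        zeros = 0
        for seed in range(7):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((60, 15))
            y = rng.standard_normal(60)
            cv = loo_rmsep(X, y, max_components=4)
            zeros += select_ncomponents(cv, rng=rng) == 0
        assert zeros >= 4


class TestScrambledNull:
    def test_marginals_preserved_exactly(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        Xn, yn = scrambled_null(X, y, rng)
        assert np.allclose(np.sort(Xn, axis=0), np.sort(X, axis=0))
        assert np.allclose(np.sort(yn), np.sort(y))

    def test_dependence_destroyed(self, rng):
        n = 2000
        base = rng.standard_normal(n)
        X = np.column_stack([base, base * 2, base + rng.standard_normal(n) * 0.1])
        y = base * 3
        Xn, yn = scrambled_null(X, y, rng)
        for j in range(3):
            assert abs(np.corrcoef(Xn[:, j], yn)[0, 1]) < 0.08
        assert abs(np.corrcoef(Xn[:, 0], Xn[:, 1])[0, 1]) < 0.08


class TestRepeatedSplits:
    def test_cohort_split_sizes(self):
        assert split_sizes(573, 0.8) == (458, 115)
        assert split_sizes(100, 0.7) == (70, 30)

    def test_ensemble_split_sizes_and_disjointness(self, rng):
        X = rng.standard_normal((573, 5))
        y = rng.standard_normal(573)
        ens = repeated_splits(X, y, n_components=2, n_reps=3, rng=rng)
        for tr, te in zip(ens.train_idx, ens.test_idx):
            assert len(tr) == 458 and len(te) == 115
            assert not set(tr) & set(te)

    def test_noise_free_linear_signal_perfect_test_correlation(self, rng):
        # at full depth PLS equals OLS, which is exact on a noise-free signal
        X = rng.standard_normal((80, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.3, -0.7, 2.0])
        ens = repeated_splits(X, y, n_components=6, n_reps=5, rng=rng)
        assert np.allclose(ens.test_r[:, -1], 1.0, atol=1e-8)

    def test_reproducible_from_seed(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        a = repeated_splits(X, y, 1, n_reps=4, rng=np.random.default_rng(3))
        b = repeated_splits(X, y, 1, n_reps=4, rng=np.random.default_rng(3))
        assert a.seed_sequence == b.seed_sequence
        assert np.array_equal(a.loadings, b.loadings)

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="train_fraction"):
            repeated_splits(rng.standard_normal((30, 3)), rng.standard_normal(30),
                            1, train_fraction=0.3, rng=rng)


class TestVarianceAccounting:
    def test_full_rank_uses_all_x_variance(self, rng):
        X = rng.standard_normal((30, 5))
        y = X @ rng.standard_normal(5) + 0.1 * rng.standard_normal(30)
        model = nipals_fit(X, y, 5)
        x_pct, y_pct = variance_accounting(model, X, y)
        assert x_pct[0] == 0.0 and y_pct[0] == 0.0
        assert x_pct[-1] == pytest.approx(100.0, abs=1e-6)

    def test_matches_reconstruction_ss_oracle(self, rng):
        X = rng.standard_normal((40, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(40)
        model = nipals_fit(X, y, 4)
        x_pct, y_pct = variance_accounting(model, X, y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        for k in range(1, 5):
            recon = model.scores[:, :k] @ model.x_loadings[:, :k].T
            expected_x = 100.0 * (1.0 - np.sum((Xc - recon) ** 2) / np.sum(Xc**2))
            assert x_pct[k] == pytest.approx(expected_x, abs=1e-8)
            yhat = model.scores[:, :k] @ model.y_loadings[:k]
            expected_y = 100.0 * (1.0 - np.sum((yc - yhat) ** 2) / np.sum(yc**2))
            assert y_pct[k] == pytest.approx(expected_y, abs=1e-8)
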