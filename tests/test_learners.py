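"""The six-method fit/predict contract and each learner's oracles."""

import numpy as np
import pytest
from scipy import optimize
from scipy.spatial.distance import cdist

from hybridgs import learners
from hybridgs.learners import BayesBHyper

SHORT_CHAIN = dict(n_iter=3000, burn_in=800, thin=4)


@pytest.fixture(scope="module")
def sparse_data():
    """n=80, m=60 panel with a handful of true QTL."""
    rng = np.random.default_rng(42)
    Z = rng.choice([-1.0, 1.0], size=(80, 60))
    qtl = np.array([3, 17, 40])
    gamma = np.array([1.2, -1.0, 0.8])
    g = Z[:, qtl] @ gamma
    y = 5.0 + g + rng.normal(0, np.sqrt(np.var(g) * 3 / 7), 80)  # h2 ~ 0.7
    return Z, y, qtl


class TestHyper:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            BayesBHyper(v=-1)
        with pytest.raises(ValueError):
            BayesBHyper(pi0=1.5)
        with pytest.raises(ValueError):
            BayesBHyper(n_iter=100, burn_in=100)


class TestLasso:
    def test_large_penalty_predicts_mean(self, sparse_data):
        Z, y, _ = sparse_data
        model = learners.fit_lasso(Z, y, lambda_=1e6)
        assert np.count_nonzero(model.effects) == 0
        np.testing.assert_allclose(model.predict(Z), np.mean(y), rtol=1e-10)

    def test_orthonormal_design_soft_threshold(self):
        """Closed-form check: with orthonormal columns the solution is the
        soft-thresholded per-marker least-squares coefficient."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((40, 5))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))  # columns orthogonal to 1
        beta = np.array([2.0, -1.5, 0.8, 0.0, 0.1])
        y = Q @ beta  # noiseless, zero-mean by construction of Q columns
        alpha = 0.02
        model = learners.fit_lasso(Q, y - y.mean(), lambda_=alpha, standardize=False)
        ols = Q.T @ (y - y.mean())
        expected = np.sign(ols) * np.maximum(np.abs(ols) - 40 * alpha, 0.0)
        np.testing.assert_allclose(model.effects, expected, atol=1e-6)

    def test_recovers_sparse_qtl(self, sparse_data):
        Z, y, qtl = sparse_data
        model = learners.fit_lasso(Z, y, cv_folds=5, seed=0)
        nonzero = set(np.flatnonzero(model.effects))
        assert set(qtl) <= nonzero

    def test_near_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((50, 8))
        y = Z @ rng.standard_normal(8) + rng.normal(0, 0.1, 50)
        model = learners.fit_lasso(Z, y, lambda_=1e-10, standardize=False)
        X = np.column_stack([np.ones(50), Z])
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(Z), X @ coef, atol=1e-4)

    def test_degenerate_phenotype_rejected(self, sparse_data):
        Z, _, _ = sparse_data
        with pytest.raises(ValueError):
            learners.fit_lasso(Z, np.ones(Z.shape[0]))


class TestBayesB:
    def test_null_data_inclusion_near_prior_mean(self):
        """With no signal the indicator posterior stays near its prior: the
        fixed slab scale is tiny relative to a field-scale residual
        variance, so the likelihood barely discriminates."""
        rng = np.random.default_rng(11)
        Z = rng.choice([-1.0, 1.0], size=(100, 100))
        y = rng.normal(50.0, 10.0, 100)
        model = learners.fit_bayesb(Z, y, BayesBHyper(seed=7, **SHORT_CHAIN))
        assert abs(model.inclusion_prob.mean() - 0.5) < 0.15

    def test_single_large_qtl_detected(self):
        rng = np.random.default_rng(5)
        Z = rng.choice([-1.0, 1.0], size=(100, 100))
        y = Z[:, 10] * 2.0 + rng.normal(0, 1.0, 100)  # ~80% variance from one QTL
        model = learners.fit_bayesb(Z, y, BayesBHyper(seed=7, **SHORT_CHAIN))
        assert model.inclusion_prob[10] > 0.95

    def test_seeded_chain_bit_reproducible(self, sparse_data):
        Z, y, _ = sparse_data
        hyper = BayesBHyper(seed=3, n_iter=400, burn_in=100, thin=2)
        m1 = learners.fit_bayesb(Z, y, hyper)
        m2 = learners.fit_bayesb(Z, y, hyper)
        assert np.array_equal(m1.effects, m2.effects)
        assert m1.intercept == m2.intercept


class TestPLS:
    def test_single_marker_equals_simple_regression(self):
        rng = np.random.default_rng(2)
        Z = rng.choice([-1.0, 0.0, 1.0], size=(30, 1))
        y = 1.0 + 2.0 * Z[:, 0] + rng.normal(0, 0.3, 30)
        model = learners.fit_pls(Z, y, max_components=1)
        slope, intercept = np.polyfit(Z[:, 0], y, 1)
        np.testing.assert_allclose(model.predict(Z), intercept + slope * Z[:, 0], atol=1e-8)

    def test_score_vectors_orthogonal(self, rng):
        Z = rng.standard_normal((30, 50))
        y = Z[:, 0] + rng.standard_normal(30)
        model = learners.fit_pls(Z, y, max_components=5, cv_folds=3)
        T = model.est.x_scores_
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8

    def test_saturated_components_match_ols(self, rng):
        Z = rng.standard_normal((40, 6))
        y = Z @ rng.standard_normal(6) + rng.normal(0, 0.5, 40)
        from sklearn.cross_decomposition import PLSRegression

        est = PLSRegression(n_components=6, scale=True).fit(Z, y)
        X = np.column_stack([np.ones(40), Z])
        ols = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(est.predict(Z).ravel(), ols, atol=1e-8)


class TestSVR:
    def test_gaussian_kernel_properties(self, rng):
        Z = rng.choice([-1.0, 1.0], size=(12, 8))
        Kh = learners.gaussian_kernel(Z, Z, h2=4.0)
        np.testing.assert_allclose(np.diag(Kh), 1.0)
        np.testing.assert_allclose(Kh, Kh.T)
        assert np.linalg.eigvalsh(Kh).min() > -1e-10

    def test_huge_epsilon_gives_constant_prediction(self, sparse_data):
        Z, y, _ = sparse_data
        model = learners.fit_svm_gauss(Z, y, epsilon=2 * np.ptp(y))
        pred = model.predict(Z)
        assert np.ptp(pred) < 1e-9

    def test_dual_objective_matches_qp_solver(self):
        """Tiny instance: sklearn's solution agrees with a generic convex QP
        solve of the epsilon-SVR dual."""
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((6, 2))
        y = Z[:, 0] + 0.2 * rng.standard_normal(6)
        C, eps, h = 2.0, 0.1, 1.5
        model = learners.fit_svm_gauss(Z, y, C=C, epsilon=eps, bandwidth=h)
        K = learners.gaussian_kernel(Z, Z, h * h)

        def neg_dual(ab):
            a, b = ab[:6], ab[6:]
            d = a - b
            return 0.5 * d @ K @ d + eps * np.sum(a + b) - y @ d

        cons = {"type": "eq", "fun": lambda ab: np.sum(ab[:6] - ab[6:])}
        res = optimize.minimize(
            neg_dual, np.full(12, C / 4), bounds=[(0, C)] * 12,
            constraints=[cons], method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        # compare dual objectives (sklearn stores dual_coef_ = a - b)
        d_sk = np.zeros(6)
        d_sk[model.est.support_] = model.est.dual_coef_.ravel()
        sk_obj = 0.5 * d_sk @ K @ d_sk + eps * np.sum(np.abs(d_sk)) - y @ d_sk
        assert abs(sk_obj - res.fun) < 1e-4


class TestRKHS:
    def test_fixed_ratio_single_kernel_equals_gblup_formula(self, sparse_data):
        Z, y, _ = sparse_data
        lam = 1.7
        model = learners.fit_rkhs(Z, y, bandwidth_multipliers=[1.0], fixed_ratios=[lam])
        n = len(y)
        sq = cdist(Z, Z, "sqeuclidean")
        Kh = np.exp(-sq / (2 * sq[np.triu_indices(n, 1)].mean()))
        V = lam * Kh + np.eye(n)
        ones = np.ones(n)
        mu = ones @ np.linalg.solve(V, y) / (ones @ np.linalg.solve(V, ones))
        oracle = mu + lam * Kh @ np.linalg.solve(V, y - mu)
        np.testing.assert_allclose(model.predict(Z), oracle, atol=1e-6)

    def test_sampled_chain_close_to_fixed_ratio_oracle(self, sparse_data):
        """Single-kernel MCMC predictions agree (within Monte-Carlo error)
        with the closed form evaluated at the chain's own mean ratio."""
        Z, y, _ = sparse_data
        model = learners.fit_rkhs(Z, y, bandwidth_multipliers=[1.0], seed=4, **SHORT_CHAIN)
        pred = model.predict(Z)
        assert np.corrcoef(pred, y)[0, 1] > 0.5
        # implied ratio from the fitted alpha: refit closed form, compare shape
        best = None
        for lam in np.logspace(-1, 1.5, 40):
            oracle = learners.fit_rkhs(Z, y, bandwidth_multipliers=[1.0], fixed_ratios=[lam])
            err = np.sqrt(np.mean((oracle.predict(Z) - pred) ** 2))
            best = min(best, err) if best is not None else err
        assert best < 0.3 * np.std(y)

    def test_seeded_chain_reproducible(self, sparse_data):
        Z, y, _ = sparse_data
        kw = dict(bandwidth_multipliers=[0.5, 2.0], n_iter=300, burn_in=50, thin=2, seed=8)
        m1 = learners.fit_rkhs(Z, y, **kw)
        m2 = learners.fit_rkhs(Z, y, **kw)
        for a, b in zip(m1.alphas, m2.alphas):
            assert np.array_equal(a, b)


class TestContract:
    @pytest.mark.parametrize("method", ["gblup", "lasso", "pls", "svm"])
    def test_row_permutation_equivariance(self, method, sparse_data):
        Z, y, _ = sparse_data
        model = learners.fit(method, Z, y, seed=0)
        perm = np.random.default_rng(0).permutation(Z.shape[0])
        np.testing.assert_allclose(
            model.predict(Z[perm]), model.predict(Z)[perm], rtol=1e-10, atol=1e-10
        )

    def test_empty_prediction_input(self, sparse_data):
        Z, y, _ = sparse_data
        model = learners.fit("gblup", Z, y)
        assert model.predict(np.empty((0, Z.shape[1]))).shape == (0,)

    def test_marker_mismatch_reported(self, tiny_bundle):
        y = tiny_bundle.hybrid_means["HI"].to_numpy()
        model = learners.fit_gblup(tiny_bundle.hybrids, y)
        shuffled = tiny_bundle.hybrids.subset_markers(
            np.roll(np.arange(tiny_bundle.hybrids.n_markers), 1)
        )
        with pytest.raises(ValueError, match="marker mismatch"):
            model.predict(shuffled)

    def test_marker_column_permutation_leaves_linear_predictions_unchanged(self, sparse_data):
        """Permuting marker columns consistently in train and test data must
        not change linear-model predictions."""
        Z, y, _ = sparse_data
        perm = np.random.default_rng(1).permutation(Z.shape[1])
        for method in ("gblup", "lasso"):
            p0 = learners.fit(method, Z, y, seed=0).predict(Z)
            p1 = learners.fit(method, Z[:, perm], y, seed=0).predict(Z[:, perm])
            np.testing.assert_allclose(p0, p1, atol=1e-6)

    def test_unknown_method_rejected(self, sparse_data):
        Z, y, _ = sparse_data
        with pytest.raises(ValueError, match="unknown method"):
            learners.fit("forest", Z, y)
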