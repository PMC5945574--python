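"""Six whole-genome predictors under one fit/predict contract.

* gblup  - kinship mixed model with profiled REML (see :mod:`hybridgs.gblup`)
* lasso  - L1-penalised marker regression, penalty chosen by internal CV
* bayesb - mixture-prior Gibbs sampler (point mass at zero + scaled
  inverse-chi-square slab on per-marker effect variances)
* pls    - partial least squares, component count chosen by internal CV
* svm    - epsilon-insensitive support vector regression, Gaussian kernel
* rkhs   - Bayesian multi-kernel Gaussian regression (kernel averaging over
  several bandwidths) fitted by Gibbs sampling

All learners accept a fully encoded genotype matrix (samples x markers,
codes -1/0/+1 or expected dosages) and a phenotype vector, and predict any
new matrix over the same markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import gblup as _gblup
from .genotype_io import GenotypeMatrix

METHODS = ("gblup", "lasso", "bayesb", "pls", "svm", "rkhs")


def _as_matrix(Z) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(Z, GenotypeMatrix):
        if not Z.is_encoded():
            raise ValueError("genotypes must be encoded (no missing calls)")
        return Z.calls, Z.marker_ids
    return np.asarray(Z, dtype=float), None


@dataclass
class BayesBHyper:
    """BayesB hyperparameters: scaled-inv-chi-square slab (v, S) on marker
    variances, Beta prior on the exclusion probability pi with mean pi0 and
    concentration p0, and chain settings."""

    v: float = 4.234
    S: float = 0.0429
    pi0: float = 0.5
    p0: float = 10.0
    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.v <= 0 or self.S <= 0:
            raise ValueError("v and S must be positive")
        if not 0 < self.pi0 < 1:
            raise ValueError("pi0 must be in (0,1)")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


class PredictorModel:
    """Fitted predictor; subclasses implement ``_predict(M)`` on raw codes."""

    method: str = ""

    def __init__(self, marker_ids: list[str] | None, training_sample_ids: list[str] | None):
        self.marker_ids = marker_ids
        self.training_sample_ids = training_sample_ids

    def predict(self, Z_new) -> np.ndarray:
        M, ids = _as_matrix(Z_new)
        if ids is not None and self.marker_ids is not None:
            if ids != self.marker_ids:
                bad = next(
                    (i, a, b)
                    for i, (a, b) in enumerate(
                        zip(ids + [None] * len(self.marker_ids), self.marker_ids + [None] * len(ids))
                    )
                    if a != b
                )
                raise ValueError(
                    f"marker mismatch at index {bad[0]}: got {bad[1]!r}, expected {bad[2]!r}"
                )
        if M.shape[0] == 0:
            return np.empty(0)
        out = np.asarray(self._predict(M), dtype=float).ravel()
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite predictions")
        return out

    def _predict(self, M: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class LinearEffectsModel(PredictorModel):
    """Predicts intercept + M @ effects; covers lasso and bayesb posterior means."""

    def __init__(self, method, intercept, effects, marker_ids=None, training_sample_ids=None):
        super().__init__(marker_ids, training_sample_ids)
        self.method = method
        self.intercept = float(intercept)
        self.effects = np.asarray(effects, dtype=float)

    def _predict(self, M):
        return self.intercept + M @ self.effects


class GBLUPModel(PredictorModel):
    method = "gblup"

    def __init__(self, fit: _gblup.GBLUPFit, Z_train: np.ndarray, marker_ids=None, training_sample_ids=None):
        super().__init__(marker_ids, training_sample_ids)
        self.fit = fit
        self.Z_train = Z_train

    def _predict(self, M):
        m = self.Z_train.shape[1]
        K_cross = (M @ self.Z_train.T) / m
        return _gblup.predict_gblup(self.fit, K_cross)


def fit_gblup(Z, y) -> GBLUPModel:
    M, marker_ids = _as_matrix(Z)
    samples = Z.samples if isinstance(Z, GenotypeMatrix) else None
    K = _gblup.compute_kinship(M)
    fit = _gblup.reml_fit(np.asarray(y, float), None, K)
    return GBLUPModel(fit, M, marker_ids, samples)


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------


def fit_lasso(
    Z,
    y,
    cv_folds: int = 5,
    lambda_: float | None = None,
    standardize: bool = True,
    seed: int = 0,
) -> LinearEffectsModel:
    """L1-penalised marker regression on a log-spaced penalty path.

    The returned model uses the penalty minimising ``cv_folds``-fold CV mean
    squared error (or a fixed ``lambda_`` if given, on scikit-learn's alpha
    scale).  Marker columns are standardised internally; effects are reported
    on the original code scale.
    """
    M, marker_ids = _as_matrix(Z)
    y = np.asarray(y, dtype=float).ravel()
    if M.shape[0] < 10 and lambda_ is None:
        raise ValueError("need n >= 10 for internal cross-validation")
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    scale = M.std(axis=0, ddof=0) if standardize else np.ones(M.shape[1])
    scale = np.where(scale == 0, 1.0, scale)
    center = M.mean(axis=0) if standardize else np.zeros(M.shape[1])
    Ms = (M - center) / scale
    if lambda_ is not None:
        est = Lasso(alpha=lambda_, max_iter=20_000, tol=1e-6)
    else:
        cv = KFold(cv_folds, shuffle=True, random_state=seed)
        est = LassoCV(alphas=100, cv=cv, max_iter=20_000, tol=1e-6)
    est.fit(Ms, y)
    effects = est.coef_ / scale
    intercept = est.intercept_ - center @ effects
    samples = Z.samples if isinstance(Z, GenotypeMatrix) else None
    return LinearEffectsModel("lasso", intercept, effects, marker_ids, samples)


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------


def _sample_scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float, size=None):
    """sigma^2 ~ df * scale / chi2_df."""
    return df * scale / rng.chisquare(df, size=size)


class BayesBModel(LinearEffectsModel):
    """Posterior-mean marker effects plus diagnostics from the Gibbs chain."""

    def __init__(self, intercept, effects, inclusion_prob, pi_mean, marker_ids=None, training_sample_ids=None):
        super().__init__("bayesb", intercept, effects, marker_ids, training_sample_ids)
        self.inclusion_prob = np.asarray(inclusion_prob, dtype=float)
        self.pi_mean = float(pi_mean)


def fit_bayesb(Z, y, hyper: BayesBHyper | None = None) -> BayesBModel:
    """Gibbs sampler for the mixture-prior marker model.

    Each marker effect gamma_k is zero with probability pi and otherwise
    N(0, sigma2_k) with sigma2_k ~ scaled-inv-chi2(v, S).  Indicators are
    updated from the likelihood with gamma_k integrated out (collapsed
    update), pi gets a Beta prior with mean pi0 and concentration p0, and
    the residual variance a Jeffreys-type update.  A fixed seed makes the
    chain bit-reproducible.
    """
    hyper = hyper or BayesBHyper()
    M, marker_ids = _as_matrix(Z)
    y = np.asarray(y, dtype=float).ravel()
    n, m = M.shape
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.Generator(np.random.PCG64(hyper.seed))

    zz = np.einsum("ij,ij->j", M, M)  # per-marker Z_k^T Z_k
    zz = np.where(zz == 0, 1e-12, zz)
    a_pi = hyper.pi0 * hyper.p0      # prior on P(excluded) = pi
    b_pi = (1 - hyper.pi0) * hyper.p0

    mu = float(np.mean(y))
    gamma = np.zeros(m)
    delta = np.zeros(m, dtype=bool)
    sig2g = _sample_scaled_inv_chi2(rng, hyper.v, hyper.S, size=m)
    sigma2 = float(np.var(y)) or 1.0
    pi = hyper.pi0
    resid = y - mu  # current residual y - mu - M @ gamma

    n_keep = 0
    gamma_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    pi_sum = 0.0

    for it in range(hyper.n_iter):
        # intercept
        mu_new = rng.normal(mu + resid.mean(), np.sqrt(sigma2 / n))
        resid -= mu_new - mu
        mu = mu_new
        # markers
        for k in range(m):
            if delta[k]:
                resid += M[:, k] * gamma[k]  # remove marker k's contribution
            ry = float(M[:, k] @ resid)
            c = zz[k] * sig2g[k] / sigma2
            # log Bayes factor: included vs excluded, gamma_k integrated out
            log_bf = -0.5 * np.log1p(c) + 0.5 * ry**2 * sig2g[k] / (sigma2 * (sigma2 + zz[k] * sig2g[k]))
            p_incl = 1.0 / (1.0 + pi / (1 - pi) * np.exp(-log_bf))
            new_delta = rng.random() < p_incl
            if new_delta:
                prec = zz[k] + sigma2 / sig2g[k]
                g_new = rng.normal(ry / prec, np.sqrt(sigma2 / prec))
                resid -= M[:, k] * g_new
            else:
                g_new = 0.0
            gamma[k] = g_new
            delta[k] = new_delta
            # marker variance: posterior if included, prior draw if excluded
            if new_delta:
                sig2g[k] = _sample_scaled_inv_chi2(
                    rng, hyper.v + 1, (hyper.v * hyper.S + g_new**2) / (hyper.v + 1)
                )
            else:
                sig2g[k] = _sample_scaled_inv_chi2(rng, hyper.v, hyper.S)
        # pi (exclusion probability)
        n_in = int(delta.sum())
        pi = rng.beta(a_pi + (m - n_in), b_pi + n_in)
        # residual variance
        sse = float(resid @ resid)
        sigma2 = float(_sample_scaled_inv_chi2(rng, n, sse / n))
        if not np.isfinite(sigma2) or not np.all(np.isfinite(gamma)):
            raise RuntimeError(f"BayesB chain diverged at iteration {it}")
        if it >= hyper.burn_in and (it - hyper.burn_in) % hyper.thin == 0:
            n_keep += 1
            gamma_sum += gamma
            incl_sum += delta
            mu_sum += mu
            pi_sum += pi

    samples = Z.samples if isinstance(Z, GenotypeMatrix) else None
    return BayesBModel(
        mu_sum / n_keep,
        gamma_sum / n_keep,
        incl_sum / n_keep,
        pi_sum / n_keep,
        marker_ids,
        samples,
    )


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


class PLSModel(PredictorModel):
    method = "pls"

    def __init__(self, est: PLSRegression, n_components: int, marker_ids=None, training_sample_ids=None):
        super().__init__(marker_ids, training_sample_ids)
        self.est = est
        self.n_components = n_components

    def _predict(self, M):
        return self.est.predict(M).ravel()


def fit_pls(Z, y, max_components: int = 10, cv_folds: int = 5, seed: int = 0) -> PLSModel:
    """PLS1 regression; component count minimises internal CV RMSE."""
    M, marker_ids = _as_matrix(Z)
    y = np.asarray(y, dtype=float).ravel()
    n, m = M.shape
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    max_components = min(max_components, n - 1, m)
    if max_components < 1:
        raise ValueError("max_components must allow at least one component")
    if max_components == 1:
        best = 1
    else:
        cv = KFold(cv_folds, shuffle=True, random_state=seed)
        errs = []
        for ncomp in range(1, max_components + 1):
            sse = 0.0
            for tr, te in cv.split(M):
                est = PLSRegression(n_components=min(ncomp, len(tr) - 1), scale=True)
                est.fit(M[tr], y[tr])
                sse += float(np.sum((est.predict(M[te]).ravel() - y[te]) ** 2))
            errs.append(sse)
        best = 1 + int(np.argmin(errs))
    est = PLSRegression(n_components=best, scale=True)
    est.fit(M, y)
    samples = Z.samples if isinstance(Z, GenotypeMatrix) else None
    return PLSModel(est, best, marker_ids, samples)


# ---------------------------------------------------------------------------
# SVR with Gaussian kernel
# ---------------------------------------------------------------------------


def median_heuristic_bandwidth(M: np.ndarray) -> float:
    """Median pairwise Euclidean distance (positive fallback if degenerate)."""
    dist = pdist(M)
    med = float(np.median(dist)) if dist.size else 1.0
    return med if med > 0 else 1.0


class SVRModel(PredictorModel):
    method = "svm"

    def __init__(self, est: SVR, bandwidth: float, marker_ids=None, training_sample_ids=None):
        super().__init__(marker_ids, training_sample_ids)
        self.est = est
        self.bandwidth = bandwidth

    def _predict(self, M):
        return self.est.predict(M)


def fit_svm_gauss(
    Z, y, C: float = 1.0, epsilon: float | None = None, bandwidth: float | str = "auto"
) -> SVRModel:
    """Epsilon-insensitive SVR with kernel exp(-||zi - zj||^2 / (2 h^2)).

    ``bandwidth="auto"`` uses the median pairwise-distance heuristic;
    ``epsilon=None`` defaults to 0.1 * sd(y).
    """
    M, marker_ids = _as_matrix(Z)
    y = np.asarray(y, dtype=float).ravel()
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon is None:
        epsilon = 0.1 * float(np.std(y))
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    h = median_heuristic_bandwidth(M) if bandwidth == "auto" else float(bandwidth)
    est = SVR(kernel="rbf", gamma=1.0 / (2.0 * h * h), C=C, epsilon=epsilon)
    est.fit(M, y)
    samples = Z.samples if isinstance(Z, GenotypeMatrix) else None
    return SVRModel(est, h, marker_ids, samples)


# ---------------------------------------------------------------------------
# RKHS (multi-kernel Bayesian Gaussian regression)
# ---------------------------------------------------------------------------


def gaussian_kernel(A: np.ndarray, B: np.ndarray, h2: float) -> np.ndarray:
    """exp(-||a-b||^2 / (2 h2)) with h2 the squared bandwidth."""
    sq = cdist(A, B, "sqeuclidean")
    return np.exp(-sq / (2.0 * h2))


class RKHSModel(PredictorModel):
    """Posterior-mean multi-kernel regression; predicts via kernel blocks
    against the stored training genotypes."""

    method = "rkhs"

    def __init__(self, mu, alphas, h2s, Z_train, marker_ids=None, training_sample_ids=None):
        super().__init__(marker_ids, training_sample_ids)
        self.mu = float(mu)
        self.alphas = [np.asarray(a, float) for a in alphas]
        self.h2s = list(h2s)
        self.Z_train = Z_train

    def _predict(self, M):
        out = np.full(M.shape[0], self.mu)
        for alpha, h2 in zip(self.alphas, self.h2s):
            out += gaussian_kernel(M, self.Z_train, h2) @ alpha
        return out


def fit_rkhs(
    Z,
    y,
    bandwidth_multipliers: Sequence[float] = (0.2, 1.0, 5.0),
    n_iter: int = 3000,
    burn_in: int = 500,
    thin: int = 5,
    seed: int = 0,
    fixed_ratios: Sequence[float] | None = None,
) -> RKHSModel:
    """Bayesian kernel regression y = mu + sum_l u_l + eps, u_l ~ N(0, s2_l K_l).

    Squared bandwidths are ``multiplier x mean squared pairwise distance``.
    Variance components get weakly informative scaled-inv-chi-square priors
    and the model is fitted by Gibbs sampling in the eigenbasis of each
    kernel.  If ``fixed_ratios`` gives s2_l / sigma2 explicitly, the posterior
    mean is computed in closed form (no sampling) -- useful for validation
    and for deterministic single-kernel regression.
    """
    if not bandwidth_multipliers:
        raise ValueError("need at least one bandwidth multiplier")
    M, marker_ids = _as_matrix(Z)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    samples = Z.samples if isinstance(Z, GenotypeMatrix) else None

    sq = cdist(M, M, "sqeuclidean")
    msd = float(sq[np.triu_indices(n, 1)].mean()) or 1.0
    h2s = [mult * msd for mult in bandwidth_multipliers]
    kernels = [np.exp(-sq / (2.0 * h2)) for h2 in h2s]

    if fixed_ratios is not None:
        if len(fixed_ratios) != len(kernels):
            raise ValueError("one ratio per kernel required")
        C = sum(r * Kl for r, Kl in zip(fixed_ratios, kernels))
        V = C + np.eye(n)
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, np.ones(n))
        mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
        w = np.linalg.solve(V, y - mu)
        alphas = [r * w for r in fixed_ratios]
        return RKHSModel(mu, alphas, h2s, M, marker_ids, samples)

    # Gibbs sampling in each kernel's eigenbasis
    eigs = []
    for Kl in kernels:
        d, U = np.linalg.eigh(Kl)
        d = np.clip(d, 0.0, None)
        if d.max() <= 0:
            raise ValueError("kernel matrix numerically zero after eigen-clipping")
        eigs.append((d, U))

    rng = np.random.Generator(np.random.PCG64(seed))
    vary = float(np.var(y)) or 1.0
    nu0, L = 5.0, len(kernels)
    S_u = vary * 0.5 / L * (nu0 + 2) / nu0   # prior mode ~ half the variance, split
    S_e = vary * 0.5 * (nu0 + 2) / nu0

    mu = float(np.mean(y))
    u = [np.zeros(n) for _ in kernels]
    s2 = [vary / (2 * L)] * L
    sigma2 = vary / 2

    keep = 0
    mu_sum = 0.0
    alpha_sums = [np.zeros(n) for _ in kernels]
    for it in range(n_iter):
        total_u = np.sum(u, axis=0)
        mu = rng.normal(np.mean(y - total_u), np.sqrt(sigma2 / n))
        for l, (d, U) in enumerate(eigs):
            e = y - mu - (total_u - u[l])
            et = U.T @ e
            lam = d * s2[l]
            post_var = lam * sigma2 / (lam + sigma2)
            post_mean = lam / (lam + sigma2) * et
            a = post_mean + np.sqrt(post_var) * rng.standard_normal(n)
            u_new = U @ a
            total_u += u_new - u[l]
            u[l] = u_new
            # variance component: quadratic form u^T K^+ u in the eigenbasis
            pos = d > 1e-10
            quad = float(np.sum(a[pos] ** 2 / d[pos]))
            df_l = nu0 + int(pos.sum())
            s2[l] = _sample_scaled_inv_chi2(rng, df_l, (nu0 * S_u + quad) / df_l)
        resid = y - mu - total_u
        sse = float(resid @ resid)
        sigma2 = _sample_scaled_inv_chi2(rng, nu0 + n, (nu0 * S_e + sse) / (nu0 + n))
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep += 1
            mu_sum += mu
            for l, (d, U) in enumerate(eigs):
                # alpha_l = K_l^+ u_l, so predictions extend via kernel blocks
                pos = d > 1e-10
                a = U.T @ u[l]
                alpha = U[:, pos] @ (a[pos] / d[pos])
                alpha_sums[l] += alpha
    return RKHSModel(
        mu_sum / keep,
        [s / keep for s in alpha_sums],
        h2s,
        M,
        marker_ids,
        samples,
    )


# ---------------------------------------------------------------------------
# factory
# ---------------------------------------------------------------------------


def fit(method: str, Z, y, seed: int = 0, **kwargs) -> PredictorModel:
    """Fit any of the six methods by name (uniform contract for CV loops)."""
    if method == "gblup":
        return fit_gblup(Z, y)
    if method == "lasso":
        return fit_lasso(Z, y, seed=seed, **kwargs)
    if method == "bayesb":
        hyper = kwargs.pop("hyper", None) or BayesBHyper(seed=seed, **kwargs)
        return fit_bayesb(Z, y, hyper)
    if method == "pls":
        return fit_pls(Z, y, seed=seed, **kwargs)
    if method == "svm":
        return fit_svm_gauss(Z, y, **kwargs)
    if method == "rkhs":
        return fit_rkhs(Z, y, seed=seed, **kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
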