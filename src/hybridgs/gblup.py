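"""Genomic BLUP: marker kinship, profiled REML for the variance ratio, prediction.

The mixed model is

    y = X beta + g + eps,   g ~ N(0, K phi^2),   eps ~ N(0, I sigma^2),

with K = (1/m) Z Z^T the marker-generated kinship (raw -1/0/+1 codes, no
centering or allele-frequency denominator) and lambda = phi^2 / sigma^2 the
single variance ratio.  beta and sigma^2 are profiled out of the restricted
likelihood analytically, leaving a one-dimensional maximisation over lambda
solved by a safeguarded Newton iteration on theta = log(lambda).

A single eigendecomposition K = U D U^T makes every likelihood evaluation
O(n), which matters because replicated cross-validation refits this model
thousands of times.

Predictions for untested individuals use only relationships:

    yhat_test = X_test beta + lambda K_cross (lambda K_train + I)^{-1} (y - X beta),

algebraically identical to ridge-regression BLUP of marker effects when the
test kinship block comes from the same (1/m) Z Z^T product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix

LAMBDA_MIN = 1e-6
LAMBDA_MAX = 1e6
_THETA_LO = np.log(LAMBDA_MIN)
_THETA_HI = np.log(LAMBDA_MAX)


class RemlConvergenceError(RuntimeError):
    def __init__(self, message: str, best_lambda: float):
        super().__init__(message)
        self.best_lambda = best_lambda


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    K: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K shape {self.K.shape} != ({n},{n})")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")

    @property
    def n(self) -> int:
        return self.K.shape[0]


def compute_kinship(Z: GenotypeMatrix | np.ndarray, sample_ids: list[str] | None = None) -> KinshipMatrix:
    """K = (1/m) Z Z^T from fully encoded genotype codes."""
    if isinstance(Z, GenotypeMatrix):
        if not Z.is_encoded():
            raise ValueError("genotypes must be encoded (no missing) for kinship")
        sample_ids = list(Z.samples)
        M = Z.calls
    else:
        M = np.asarray(Z, dtype=float)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(M.shape[0])]
    n, m = M.shape
    if m == 0:
        raise ValueError("kinship requires at least one marker")
    K = (M @ M.T) / m
    K = (K + K.T) / 2.0  # exact symmetry against roundoff
    return KinshipMatrix(sample_ids, K)


@dataclass
class GBLUPFit:
    """Fitted GBLUP state, sufficient to predict new individuals."""

    lambda_hat: float
    sigma2_hat: float
    phi2_hat: float
    beta_hat: np.ndarray
    restricted_loglik: float
    y_train: np.ndarray
    X_train: np.ndarray
    K_train: KinshipMatrix
    n: int
    q: int
    # cached (lambda K + I)^{-1} (y - X beta) for prediction
    _w_resid: np.ndarray | None = None


def _eigen_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-8:
        raise ValueError(f"kinship not PSD: min eigenvalue {d.min():.3e}")
    return np.clip(d, 0.0, None), U


def _profile(theta: float, d: np.ndarray, Xt: np.ndarray, yt: np.ndarray, n: int, q: int):
    """Profiled restricted log-likelihood and ingredients at theta = log lambda.

    Works in the eigenbasis of K where (lambda K + I)^{-1} is diagonal with
    weights w_i = 1 / (lambda d_i + 1).
    """
    lam = np.exp(theta)
    w = 1.0 / (lam * d + 1.0)
    A = (Xt * w[:, None]).T @ Xt          # X^T H^{-1} X
    bvec = (Xt * w[:, None]).T @ yt       # X^T H^{-1} y
    beta = np.linalg.solve(A, bvec)
    r = yt - Xt @ beta
    s = float(np.sum(w * r * r))          # (y-Xb)^T H^{-1} (y-Xb)
    sigma2 = s / (n - q)
    sign, logdetA = np.linalg.slogdet(A)
    logdetH = float(np.sum(np.log(lam * d + 1.0)))
    ll = -0.5 * (logdetH + logdetA + (n - q) * np.log(s))
    return ll, lam, w, beta, r, s, sigma2


def _profile_grad(theta: float, d: np.ndarray, Xt: np.ndarray, yt: np.ndarray, n: int, q: int) -> float:
    """Analytic dL/dtheta of the profiled restricted log-likelihood."""
    ll, lam, w, beta, r, s, _ = _profile(theta, d, Xt, yt, n, q)
    dw = -d * w * w                       # dw_i/dlambda
    # d logdetH
    t1 = float(np.sum(d * w))
    # d logdet(X^T H^{-1} X) = tr(A^{-1} dA),  dA = X^T diag(dw) X
    A = (Xt * w[:, None]).T @ Xt
    dA = (Xt * dw[:, None]).T @ Xt
    t2 = float(np.trace(np.linalg.solve(A, dA)))
    # ds/dlambda by envelope theorem
    ds = float(np.sum(dw * r * r))
    dl_dlam = -0.5 * (t1 + t2 + (n - q) * ds / s)
    return dl_dlam * lam                  # chain rule to theta


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    K: KinshipMatrix,
    max_iter: int = 100,
    tol_theta: float = 1e-8,
) -> GBLUPFit:
    """Maximise the profiled restricted likelihood over the variance ratio.

    Safeguarded Newton on theta = log(lambda) within [log 1e-6, log 1e6]:
    a coarse scan brackets a sign change of dL/dtheta, then Newton steps
    (finite-difference curvature of the analytic gradient) are taken only if
    they stay inside the bracket; otherwise bisect.  A maximum on the boundary
    is reported, not an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    q = X.shape[1]
    if n != K.n or X.shape[0] != n:
        raise ValueError("dimension mismatch between y, X and K")
    if np.linalg.matrix_rank(X) < q or q >= n:
        raise ValueError("X must have full column rank with q < n")

    d, U = _eigen_kinship(K.K)
    yt = U.T @ y
    Xt = U.T @ X

    def g(theta):
        return _profile_grad(theta, d, Xt, yt, n, q)

    # coarse scan for a bracket of the stationary point
    grid = np.linspace(_THETA_LO, _THETA_HI, 49)
    gv = np.array([g(t) for t in grid])
    if gv[0] <= 0:          # decreasing at the lower bound -> boundary maximum
        theta_hat = _THETA_LO
    elif gv[-1] >= 0:       # still increasing at the upper bound
        theta_hat = _THETA_HI
    else:
        i = int(np.flatnonzero((gv[:-1] > 0) & (gv[1:] <= 0))[0])
        lo, hi = grid[i], grid[i + 1]
        theta = 0.5 * (lo + hi)
        converged = False
        for _ in range(max_iter):
            gt = g(theta)
            if gt > 0:
                lo = theta
            else:
                hi = theta
            h = 1e-6
            curv = (g(theta + h) - g(theta - h)) / (2 * h)
            step = -gt / curv if curv < 0 else np.nan
            new = theta + step
            if not np.isfinite(new) or not (lo < new < hi):
                new = 0.5 * (lo + hi)   # bisection fallback
            if abs(new - theta) < tol_theta or (hi - lo) < tol_theta:
                theta = new
                converged = True
                break
            theta = new
        if not converged and (hi - lo) > 1e-4:
            raise RemlConvergenceError(
                f"REML did not converge in {max_iter} iterations", float(np.exp(theta))
            )
        theta_hat = theta

    ll, lam, w, beta, r, s, sigma2 = _profile(theta_hat, d, Xt, yt, n, q)
    lam_hat = 0.0 if lam <= LAMBDA_MIN * (1 + 1e-9) else float(lam)
    if lam_hat == 0.0:
        # re-evaluate at exactly lambda = 0 for clean boundary reporting
        w = np.ones_like(d)
        A = Xt.T @ Xt
        beta = np.linalg.solve(A, Xt.T @ yt)
        r = yt - Xt @ beta
        s = float(r @ r)
        sigma2 = s / (n - q)
    fit = GBLUPFit(
        lambda_hat=lam_hat,
        sigma2_hat=float(sigma2),
        phi2_hat=lam_hat * float(sigma2),
        beta_hat=beta,
        restricted_loglik=float(ll),
        y_train=y,
        X_train=X,
        K_train=K,
        n=n,
        q=q,
    )
    fit._w_resid = U @ (w * r)            # (lambda K + I)^{-1} (y - X beta)
    return fit


def profiled_loglik(lam: float, y: np.ndarray, X: np.ndarray | None, K: KinshipMatrix) -> float:
    """Evaluate the profiled restricted log-likelihood at a given lambda."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    d, U = _eigen_kinship(K.K)
    ll, *_ = _profile(np.log(lam), d, U.T @ X, U.T @ y, n, X.shape[1])
    return ll


def predict_gblup(
    fit: GBLUPFit, K_cross: np.ndarray, X_test: np.ndarray | None = None
) -> np.ndarray:
    """Predict test individuals from their kinship with the training set.

    ``K_cross`` is the test x train kinship block, columns ordered as the
    fit's training samples.  With intercept-only fixed effects the fixed part
    is the scalar intercept.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != fit.n:
        raise ValueError(
            f"K_cross has {K_cross.shape[1]} columns; expected {fit.n} training samples"
        )
    if X_test is None:
        X_test = np.ones((K_cross.shape[0], fit.q))
    fixed = np.asarray(X_test, dtype=float) @ fit.beta_hat
    if fit.lambda_hat == 0.0:
        return fixed
    if fit._w_resid is None:  # recompute if the cache was dropped
        H = fit.lambda_hat * fit.K_train.K + np.eye(fit.n)
        fit._w_resid = np.linalg.solve(H, fit.y_train - fit.X_train @ fit.beta_hat)
    return fixed + fit.lambda_hat * (K_cross @ fit._w_resid)
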