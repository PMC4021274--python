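"""Proper univariate multiple-imputation methods for a bounded score.

Four imputation methods, each drawing fresh model parameters for every
imputed copy (proper imputation, so between-imputation variance reflects
parameter uncertainty):

* ``regress`` — Bayesian linear regression under the noninformative prior;
  imputed values may fall outside the score's range and are retained.
* ``regress_round`` — the same draws, then clamped ("rounded") to the range
  limits.
* ``truncreg`` — truncated-normal regression: ML fit of a normal linear
  model renormalized to [lo, hi], asymptotic-normal parameter draws, and
  inverse-CDF sampling within the bounds.
* ``pmm`` — predictive mean matching with k nearest donor candidates.

Each method can operate on the raw scale or after a zero-skewness shifted
log transform (with the bounds mapped to the transformed scale where the
method uses bounds, and imputations mapped back afterwards without
clipping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr, ndtri

from .data import CompleteDataset, design_matrix
from .transform import apply_transform, fit_zero_skew, invert_transform

METHODS = ("regress", "regress_round", "truncreg", "pmm")
SCALES = ("raw", "transformed")


class ImputationError(RuntimeError):
    """Degenerate fit or failed convergence; the replicate should be
    recorded as failed for this method, never silently imputed."""


@dataclass(frozen=True)
class ParameterDraw:
    """One proper-imputation draw of regression parameters."""

    beta_star: np.ndarray
    sigma_star: float
    source: str = "bayes_normal"

    def __post_init__(self) -> None:
        if not self.sigma_star > 0:
            raise ImputationError("sigma draw must be positive")


@dataclass(frozen=True)
class TruncregFit:
    """ML fit of the truncated-normal regression, with asymptotic covariance
    of (beta, ln sigma)."""

    beta: np.ndarray
    sigma: float
    cov: np.ndarray
    lo: float
    hi: float


@dataclass(frozen=True)
class CompletedSet:
    """m completed copies of the score plus out-of-range bookkeeping.

    ``n_below`` / ``n_above`` count imputed values outside the bounds on the
    imputation scale, recorded before any rounding or back-transform.
    """

    imputations: np.ndarray  # (m, n)
    mask: np.ndarray
    method: str
    scale: str
    lo: float
    hi: float
    n_below: np.ndarray
    n_above: np.ndarray

    def __post_init__(self) -> None:
        if self.imputations.shape[0] < 2:
            raise ValueError("need m >= 2 imputed copies")

    @property
    def m(self) -> int:
        return self.imputations.shape[0]

    @property
    def n_imputed(self) -> int:
        return int(self.mask.sum())

    def to_long_frame(self):
        """Stack the m copies in long format with a copy-index column."""
        import pandas as pd
        m, n = self.imputations.shape
        return pd.DataFrame({
            "imputation": np.repeat(np.arange(1, m + 1), n),
            "row": np.tile(np.arange(n), m),
            "score": self.imputations.ravel(),
            "imputed": np.tile(self.mask, m),
        })


# ---------------------------------------------------------------------------
# Bayesian linear regression draws

def _ls_fit(y: np.ndarray, X: np.ndarray):
    n, p = X.shape
    if n <= p:
        raise ImputationError("fewer observed rows than parameters")
    R = np.linalg.qr(X, mode="r")
    if np.abs(np.diag(R)).min() < 1e-10 * np.abs(np.diag(R)).max():
        raise ImputationError("design matrix is rank deficient on observed rows")
    beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    return beta_hat, rss, R


def draw_bayes_linreg(y_obs: np.ndarray, X_obs: np.ndarray,
                      rng: np.random.Generator) -> ParameterDraw:
    """Proper-imputation posterior draw under the noninformative prior.

    sigma*^2 = RSS / chi2_{n-p}; beta* ~ N(beta_hat, sigma*^2 (X'X)^{-1}).
    """
    n, p = X_obs.shape
    beta_hat, rss, R = _ls_fit(y_obs, X_obs)
    if rss <= 1e-12 * max(1.0, float(y_obs @ y_obs)):
        raise ImputationError("residual sum of squares is zero; "
                              "posterior for sigma is degenerate")
    nu = n - p
    sigma_star = float(np.sqrt(rss / rng.chisquare(nu)))
    # (X'X)^{-1} = R^{-1} R^{-T}; draw beta* = beta_hat + sigma* R^{-1} z
    z = rng.standard_normal(p)
    beta_star = beta_hat + sigma_star * solve_triangular(R, z, lower=False)
    return ParameterDraw(beta_star=beta_star, sigma_star=sigma_star)


def impute_regress(y_obs: np.ndarray, X: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One linear-regression imputation copy; out-of-range values retained."""
    mask = np.asarray(mask, dtype=bool)
    y = np.empty(mask.size)
    y[~mask] = y_obs
    if not mask.any():
        return y
    draw = draw_bayes_linreg(y_obs, X[~mask], rng)
    mu = X[mask] @ draw.beta_star
    y[mask] = mu + draw.sigma_star * rng.standard_normal(mask.sum())
    return y


def round_to_bounds(y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clamp values to the range limits (post-imputation rounding)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    return np.clip(y, lo, hi)


# ---------------------------------------------------------------------------
# Truncated-normal regression

def _trunc_loglik_terms(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                        lo: float, hi: float):
    beta, s = theta[:-1], theta[-1]
    sigma = np.exp(s)
    mu = X @ beta
    z = (y - mu) / sigma
    a = np.full_like(mu, -np.inf) if np.isneginf(lo) else (lo - mu) / sigma
    b = np.full_like(mu, np.inf) if np.isposinf(hi) else (hi - mu) / sigma
    return sigma, z, a, b, _log_trunc_mass(a, b)


def _logsubexp(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = la + np.log1p(-np.exp(lb - la))
    return np.where(np.isneginf(lb), la, out)


def _log_trunc_mass(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) stably in both tails.

    In the right tail (a > 0) the difference of CDFs cancels
    catastrophically, so it is computed from survival functions instead:
    Phi(b) - Phi(a) = Phibar(a) - Phibar(b).
    """
    right = a > 0
    out = np.empty(np.broadcast(a, b).shape)
    out[~right] = _logsubexp(log_ndtr(b[~right]), log_ndtr(a[~right]))
    out[right] = _logsubexp(log_ndtr(-a[right]), log_ndtr(-b[right]))
    return out


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _log_phi(x: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(x), -np.inf)
    finite = np.isfinite(x)
    out[finite] = -0.5 * np.asarray(x)[finite] ** 2 - _LOG_SQRT_2PI
    return out


def trunc_nll(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
              lo: float, hi: float) -> float:
    """Negative truncated-normal log-likelihood in (beta, ln sigma)."""
    sigma, z, a, b, log_z_mass = _trunc_loglik_terms(theta, y, X, lo, hi)
    ll = -0.5 * z ** 2 - _LOG_SQRT_2PI - np.log(sigma) - log_z_mass
    return float(-np.sum(ll))


def trunc_nll_grad(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                   lo: float, hi: float) -> np.ndarray:
    """Analytic gradient of :func:`trunc_nll`.

    Hazard-like ratios phi(.)/(Phi(b)-Phi(a)) are formed in log space so the
    gradient stays finite even when the truncation interval carries almost
    no normal mass (the ridge toward the exponential limit).
    """
    sigma, z, a, b, log_z_mass = _trunc_loglik_terms(theta, y, X, lo, hi)
    r_a = np.exp(_log_phi(a) - log_z_mass)  # phi(a) / mass
    r_b = np.exp(_log_phi(b) - log_z_mass)
    a_r_a = np.where(np.isfinite(a), a, 0.0) * r_a
    b_r_b = np.where(np.isfinite(b), b, 0.0) * r_b
    dl_dmu = (z + r_b - r_a) / sigma
    dl_ds = z ** 2 - 1.0 + b_r_b - a_r_a
    grad = np.empty(theta.size)
    grad[:-1] = X.T @ dl_dmu
    grad[-1] = np.sum(dl_ds)
    return -grad


def _numeric_hessian(grad, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = h * max(1.0, abs(theta[j]))
        H[:, j] = (grad(theta + step) - grad(theta - step)) / (2 * step[j])
    return 0.5 * (H + H.T)


def fit_truncreg_ml(y_obs: np.ndarray, X_obs: np.ndarray,
                    lo: float, hi: float, max_restarts: int = 3
                    ) -> TruncregFit:
    """Maximum-likelihood fit of the truncated-normal regression.

    The truncation model assigns probability only to lo < y < hi, so
    observations at or beyond the limits are excluded from the likelihood —
    the behaviour of standard truncated-regression tools. On scores with a
    point mass at a bound this discards that mass, which is precisely why
    the method imputes too high on severely skewed data.

    Optimizes in (beta, ln sigma) from a least-squares start; the covariance
    is the inverse observed information (numerically differenced analytic
    gradient). Non-convergence after restarts raises
    :class:`ImputationError` so the caller can record a failed replicate.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    if y_obs.min() < lo or y_obs.max() > hi:
        raise ValueError("observed values must lie within [lo, hi]")
    interior = (y_obs > lo) & (y_obs < hi)
    y_obs, X_obs = y_obs[interior], X_obs[interior]
    n, p = X_obs.shape
    if n <= p + 1:
        raise ImputationError("too few strictly interior observed rows "
                              "for the truncated fit")
    beta0, rss, _ = _ls_fit(y_obs, X_obs)
    s0 = 0.5 * np.log(max(rss / n, 1e-12))
    start = np.append(beta0, s0)
    args = (y_obs, X_obs, lo, hi)
    # Box keeping the search where the likelihood is computable: on severely
    # skewed data the MLE can escape along the ridge toward the exponential
    # limit (mu -> -inf, sigma -> inf); the box caps that excursion and the
    # fit then stops by relative-likelihood convergence, as reference
    # truncated-regression implementations do in practice.
    halfwidth = 100.0 * max(np.exp(s0), 1.0)
    box = [(b - halfwidth, b + halfwidth) for b in beta0] + [(s0 - 4.0, s0 + 4.0)]
    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    for attempt in range(max_restarts + 1):
        theta0 = start if attempt == 0 else start + 0.1 * attempt * rng.standard_normal(start.size)
        res = minimize(trunc_nll, theta0, args=args, jac=trunc_nll_grad,
                       method="L-BFGS-B", bounds=box,
                       options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-9})
        if res.success and np.isfinite(res.fun):
            best = res
            break
    if best is None:
        raise ImputationError("truncated-normal ML fit failed to converge")
    H = _numeric_hessian(lambda t: trunc_nll_grad(t, *args), best.x)
    try:
        L = cholesky(H, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ImputationError("observed information not positive definite") from exc
    cov = cho_solve((L, True), np.eye(H.shape[0]))
    return TruncregFit(beta=best.x[:-1], sigma=float(np.exp(best.x[-1])),
                       cov=cov, lo=lo, hi=hi)


def sample_truncnorm(mu: np.ndarray, sigma: float, lo: float, hi: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from N(mu, sigma^2) truncated to [lo, hi]."""
    mu = np.asarray(mu, dtype=float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    mass = ndtr(b) - ndtr(a)
    if np.any(mass < 1e-30):
        raise ImputationError("truncation bounds too far in the tail "
                              "(normal mass underflow)")
    u = rng.random(mu.size)
    y = mu + sigma * ndtri(ndtr(a) + u * mass)
    return np.clip(y, lo, hi)  # guard float round-off at the edges


def impute_truncreg(fit: TruncregFit, X: np.ndarray, mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """One truncated-regression imputation copy; values in [lo, hi] by
    construction. The full imputed vector is returned with observed entries
    untouched (caller supplies them)."""
    mask = np.asarray(mask, dtype=bool)
    theta_hat = np.append(fit.beta, np.log(fit.sigma))
    try:
        L = cholesky(fit.cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ImputationError("covariance not positive definite") from exc
    theta_star = theta_hat + L @ rng.standard_normal(theta_hat.size)
    beta_star, sigma_star = theta_star[:-1], float(np.exp(theta_star[-1]))
    y = np.full(mask.size, np.nan)
    if mask.any():
        mu = X[mask] @ beta_star
        y[mask] = sample_truncnorm(mu, sigma_star, fit.lo, fit.hi, rng)
    return y


# ---------------------------------------------------------------------------
# Predictive mean matching

def impute_pmm(y_obs: np.ndarray, X: np.ndarray, mask: np.ndarray,
               rng: np.random.Generator, k: int = 5,
               matching: str = "type1") -> np.ndarray:
    """One predictive-mean-matching copy with k nearest donor candidates.

    Predicted means use a fresh parameter draw beta* for the missing rows
    and the least-squares beta_hat for the donors (type-1 matching; type-0
    uses beta_hat for both). For each missing row the k observed rows with
    the smallest |yhat_mis - yhat_obs| are candidates (ties broken by a
    seeded shuffle) and the imputed value is a uniformly chosen donor's
    observed value — hence always inside the observed range.
    """
    mask = np.asarray(mask, dtype=bool)
    y_obs = np.asarray(y_obs, dtype=float)
    n_obs = y_obs.size
    if k > n_obs:
        raise ImputationError(f"k={k} exceeds the {n_obs} observed rows")
    if matching not in ("type0", "type1"):
        raise ValueError("matching must be 'type0' or 'type1'")
    y = np.empty(mask.size)
    y[~mask] = y_obs
    if not mask.any():
        return y
    X_obs = X[~mask]
    beta_hat, _, _ = _ls_fit(y_obs, X_obs)
    if matching == "type1":
        beta_mis = draw_bayes_linreg(y_obs, X_obs, rng).beta_star
    else:
        beta_mis = beta_hat
    yhat_mis = X[mask] @ beta_mis
    yhat_obs = X_obs @ beta_hat
    dist = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
    # independent tie-break shuffle per missing row: with discrete
    # covariates many donors are exactly equidistant, and reusing one
    # candidate set across rows would correlate the donations
    keys = rng.random(dist.shape)
    order = np.lexsort((keys, dist), axis=1)[:, :k]
    pick = rng.integers(k, size=order.shape[0])
    y[mask] = y_obs[order[np.arange(order.shape[0]), pick]]
    return y


# ---------------------------------------------------------------------------
# Orchestration

def multiple_impute(data: CompleteDataset, mask: np.ndarray, method: str,
                    scale: str = "raw", m: int = 20, k: int = 5,
                    rng: int | np.random.Generator | None = None,
                    matching: str = "type1") -> CompletedSet:
    """Produce m completed copies of the score by one method on one scale.

    On the transformed scale the zero-skewness shift is fitted to the
    observed (post-missingness) values, bounds are mapped across, imputation
    happens there, and imputed values are mapped back without clipping.
    Out-of-range counts are recorded on the imputation scale before any
    rounding or back-transform.
    """
    from .data import as_rng
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    if m < 2:
        raise ValueError("need m >= 2")
    rng = as_rng(rng)
    mask = np.asarray(mask, dtype=bool)
    X = design_matrix(data.outcome, data.aux)
    obs = ~mask

    if scale == "transformed":
        tspec = fit_zero_skew(data.score[obs], lo=data.lo, hi=data.hi)
        y_obs = apply_transform(data.score[obs], tspec)
        lo_s, hi_s = tspec.lo_t, tspec.hi_t
    else:
        tspec = None
        y_obs = data.score[obs]
        lo_s, hi_s = data.lo, data.hi

    fit = None
    if method == "truncreg":
        fit = fit_truncreg_ml(y_obs, X[obs], lo_s, hi_s)

    copies = np.empty((m, data.n))
    n_below = np.zeros(m, dtype=int)
    n_above = np.zeros(m, dtype=int)
    for i in range(m):
        if method in ("regress", "regress_round"):
            y = impute_regress(y_obs, X, mask, rng)
        elif method == "truncreg":
            y = impute_truncreg(fit, X, mask, rng)
            y[obs] = y_obs
        else:
            y = impute_pmm(y_obs, X, mask, rng, k=k, matching=matching)
        n_below[i] = int(np.sum(y[mask] < lo_s))
        n_above[i] = int(np.sum(y[mask] > hi_s))
        if method == "regress_round":
            y[mask] = round_to_bounds(y[mask], lo_s, hi_s)
        if tspec is not None:
            y[mask] = invert_transform(y[mask], tspec)
        copies[i] = y
        copies[i, obs] = data.score[obs]  # observed entries exact on raw scale
    return CompletedSet(imputations=copies, mask=mask, method=method,
                        scale=scale, lo=data.lo, hi=data.hi,
                        n_below=n_below, n_above=n_above)
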