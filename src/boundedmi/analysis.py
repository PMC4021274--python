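"""Complete-data target analyses and Rubin's-rules pooling.

Two target parameters: the marginal mean of the score, and the slope (log
odds ratio) of a univariable logistic regression of the binary outcome on
the score. Per-copy estimates are pooled with Rubin's rules.

The default 95% interval is the one evaluated by the missingness-resampling
design: with the complete-data estimate Q_hat held fixed, the only
variability of Qbar_m is between-imputation noise, so the interval is

    Qbar_m -/+ sqrt((1 + 1/m) B_m) * t_{m-1, 0.975}.

The standard total-variance MI interval for real-data inference,
Qbar_m -/+ sqrt(Ubar_m + (1 + 1/m) B_m) * t, is available via
``interval="total"``, and the classic Rubin (1987) degrees of freedom via
``df="rubin"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import t as t_dist

PARAMETERS = ("marginal_mean", "log_odds_ratio")


@dataclass(frozen=True)
class EstimateSE:
    """A point estimate and its squared standard error."""

    estimate: float
    variance: float
    parameter: str

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class PooledResult:
    """Rubin's-rules pooled summary of m per-copy estimates."""

    q_bar: float
    u_bar: float
    b_m: float
    total_var: float
    ci_lo: float
    ci_hi: float
    m: int
    parameter: str

    def covers(self, q_hat: float) -> bool:
        """Whether the closed interval [ci_lo, ci_hi] contains q_hat."""
        return self.ci_lo <= q_hat <= self.ci_hi


def analyze_marginal_mean(score: np.ndarray) -> EstimateSE:
    """Sample mean with variance s^2/n (unbiased sample variance)."""
    score = np.asarray(score, dtype=float)
    n = score.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    var = float(np.var(score, ddof=1)) / n
    if var == 0:
        raise ValueError("constant score: variance of the mean is zero")
    return EstimateSE(estimate=float(score.mean()), variance=var,
                      parameter="marginal_mean")


def analyze_logistic(outcome: np.ndarray, score: np.ndarray,
                     tol: float = 1e-8, max_iter: int = 50) -> EstimateSE:
    """Univariable logistic regression slope by Newton-Raphson.

    Returns the score coefficient (log odds ratio per score unit) and its
    squared asymptotic standard error from the inverse observed information.
    Raises on separation or non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(score, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        if w.min() < 1e-12 or np.abs(beta).max() > 30:
            raise ValueError("(quasi-)separation detected in logistic fit")
        grad = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        step = np.linalg.solve(info, grad)
        beta += step
        if abs(step[1]) < tol:
            p = expit(X @ beta)
            info = (X * (p * (1 - p))[:, None]).T @ X
            var = float(np.linalg.inv(info)[1, 1])
            return EstimateSE(estimate=float(beta[1]), variance=var,
                              parameter="log_odds_ratio")
    raise ValueError("logistic fit did not converge")


def analyze(score: np.ndarray, outcome: np.ndarray,
            parameter: str) -> EstimateSE:
    """Dispatch to the analysis for one target parameter."""
    if parameter == "marginal_mean":
        return analyze_marginal_mean(score)
    if parameter == "log_odds_ratio":
        return analyze_logistic(outcome, score)
    raise ValueError(f"unknown parameter {parameter!r}")


def rubin_pool(per_copy: list[EstimateSE], df: str = "m_minus_1",
               interval: str = "between") -> PooledResult:
    """Pool m per-copy estimates with Rubin's rules.

    ``interval='between'`` (default) builds the missingness-resampling
    evaluation interval with half-width sqrt((1 + 1/m) Bm) * t;
    ``interval='total'`` the standard MI interval with half-width
    sqrt(Ubar + (1 + 1/m) Bm) * t. ``df='m_minus_1'`` uses t with m - 1
    degrees of freedom; ``df='rubin'`` the classic
    nu = (m - 1)(1 + Ubar/((1 + 1/m) Bm))^2.
    """
    m = len(per_copy)
    if m < 2:
        raise ValueError("need m >= 2 per-copy estimates to pool")
    params = {e.parameter for e in per_copy}
    if len(params) > 1:
        raise ValueError(f"mixed parameter types: {sorted(params)}")
    q = np.array([e.estimate for e in per_copy])
    u = np.array([e.variance for e in per_copy])
    q_bar = float(q.mean())
    u_bar = float(u.mean())
    b_m = float(np.var(q, ddof=1))
    total = u_bar + (1.0 + 1.0 / m) * b_m
    if df == "m_minus_1":
        nu = m - 1
    elif df == "rubin":
        incr = (1.0 + 1.0 / m) * b_m
        nu = np.inf if incr == 0 else (m - 1) * (1.0 + u_bar / incr) ** 2
    else:
        raise ValueError("df must be 'm_minus_1' or 'rubin'")
    if interval == "between":
        width_var = (1.0 + 1.0 / m) * b_m
    elif interval == "total":
        width_var = total
    else:
        raise ValueError("interval must be 'between' or 'total'")
    half = float(np.sqrt(width_var) * t_dist.ppf(0.975, nu))
    return PooledResult(q_bar=q_bar, u_bar=u_bar, b_m=b_m, total_var=total,
                        ci_lo=q_bar - half, ci_hi=q_bar + half, m=m,
                        parameter=params.pop())
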