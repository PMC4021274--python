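"""MCAR and MAR missingness mechanisms for the bounded score.

Only the score is ever set to missing; the binary outcome and the 4-level
auxiliary stay complete. Under MAR the per-person missingness probability
follows a logistic model in the outcome and auxiliary indicators,

    logit Pr(missing_i) = alpha + b1*Living_i + b2*1{aux=moderate}
                          + b3*1{aux=high} + b4*1{aux=very_high},

with slope coefficients fixed (defaults b1=1.25, an odds ratio of 3.5, and
b2=0.2, b3=0.3, b4=0.4) and the intercept alpha calibrated empirically so
the mean missingness probability over the complete dataset equals the
target proportion (default 0.33).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data import CompleteDataset, as_rng

ALPHA_TOL = 1e-6  # absolute tolerance on the calibrated mean probability


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism, target proportion and MAR logistic coefficients."""

    mechanism: str = "MCAR"
    prop: float = 0.33
    beta_living: float = 1.25
    beta_aux_moderate: float = 0.2
    beta_aux_high: float = 0.3
    beta_aux_veryhigh: float = 0.4
    alpha: float | None = None
    #: MCAR sampling style: "fixed" masks exactly round(prop*n) scores,
    #: "bernoulli" draws independent indicators like the MAR mechanism.
    mcar_style: str = "fixed"

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be 'MCAR' or 'MAR'")
        if not 0.0 < self.prop < 1.0:
            raise ValueError("prop must lie in (0, 1)")
        if self.mcar_style not in ("fixed", "bernoulli"):
            raise ValueError("mcar_style must be 'fixed' or 'bernoulli'")


@dataclass(frozen=True)
class MissingMask:
    """Boolean score-missingness indicator plus bookkeeping."""

    mask: np.ndarray
    mechanism: str
    realized_prop: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def _linear_predictor(outcome: np.ndarray, aux: np.ndarray,
                      spec: MissingnessSpec) -> np.ndarray:
    outcome = np.asarray(outcome, dtype=float)
    aux = np.asarray(aux, dtype=int)
    betas = np.array([spec.beta_aux_moderate, spec.beta_aux_high,
                      spec.beta_aux_veryhigh])
    eta = spec.beta_living * outcome
    nonref = aux > 0
    eta[nonref] += betas[aux[nonref] - 1]
    return eta


def mar_probability(outcome: np.ndarray, aux: np.ndarray,
                    spec: MissingnessSpec) -> np.ndarray:
    """Per-person MAR missingness probabilities expit(alpha + beta'x)."""
    if spec.alpha is None:
        raise ValueError("alpha is unset; run calibrate_alpha first")
    return expit(spec.alpha + _linear_predictor(outcome, aux, spec))


def calibrate_alpha(data: CompleteDataset,
                    spec: MissingnessSpec) -> MissingnessSpec:
    """Choose alpha so the mean missingness probability equals ``spec.prop``.

    The mean of expit(alpha + eta_i) is continuous and strictly increasing
    in alpha with range (0, 1), so a unique root always exists; it is found
    by bracketed root search to within ``ALPHA_TOL`` on the mean probability.
    """
    eta = _linear_predictor(data.outcome, data.aux, spec)
    if np.ptp(eta) == 0:  # all-equal predictors: closed form
        return replace(spec, alpha=float(logit(spec.prop) - eta[0]))

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta)) - spec.prop)

    lo = logit(spec.prop) - eta.max()
    hi = logit(spec.prop) - eta.min()
    alpha = brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(gap(alpha)) < ALPHA_TOL
    return replace(spec, alpha=float(alpha))


def impose(data: CompleteDataset, spec: MissingnessSpec,
           seed: int | np.random.Generator | None = None) -> MissingMask:
    """Draw one missingness mask for the score.

    MCAR (default style): a simple random sample of exactly round(prop*n)
    indices. MAR: independent Bernoulli draws with the calibrated logistic
    probabilities.
    """
    rng = as_rng(seed)
    n = data.n
    mask = np.zeros(n, dtype=bool)
    if spec.mechanism == "MCAR":
        if spec.mcar_style == "fixed":
            n_miss = int(round(spec.prop * n))
            mask[rng.choice(n, size=n_miss, replace=False)] = True
        else:
            mask = rng.random(n) < spec.prop
    else:
        p = mar_probability(data.outcome, data.aux, spec)
        mask = rng.random(n) < p
    return MissingMask(mask=mask, mechanism=spec.mechanism,
                       realized_prop=float(mask.mean()))
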