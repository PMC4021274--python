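"""Zero-skewness shifted log transform for positively skewed bounded scores.

Finds the shift k < min(x) such that ln(x - k) has zero sample skewness
(moment coefficient g1 = m3 / m2^{3/2}), the same criterion as the classic
"lnskew0" procedure. The hard range limits of the score are mapped to the
transformed scale, lo_t = ln(lo - k) and hi_t = ln(hi - k), so that bounded
imputation methods can operate there; the transform pair is exactly
invertible, so back-transformed imputations outside the range stay outside
(no clipping happens here — instability of the back-transform on severely
skewed data is a finding, not a bug).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import skew

SKEW_TOL = 1e-6


@dataclass(frozen=True)
class TransformSpec:
    """Fitted shifted-log transform: y = ln(x - shift)."""

    shift: float
    lo: float
    hi: float
    lo_t: float
    hi_t: float
    direction: str = "ln_shift"


def fit_zero_skew(x: np.ndarray, lo: float | None = None,
                  hi: float | None = None) -> TransformSpec:
    """Fit the shift k so that ln(x - k) has zero sample skewness.

    As k decreases toward -inf, ln(x - k) becomes an affine function of x
    and its skewness approaches the (positive) raw skewness; as k increases
    toward min(x), the skewness diverges to -inf. A sign change is therefore
    bracketed and the root located to |g1| < 1e-6.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct values to fit the shift")
    raw_skew = skew(x)
    if raw_skew <= 0:
        raise ValueError("zero-skewness log transform requires positive "
                         f"raw skewness (got g1={raw_skew:.4f})")
    xmin = x.min()
    lo = xmin if lo is None else float(lo)
    hi = x.max() if hi is None else float(hi)
    upper = min(xmin, lo)  # keep lo - k > 0 so both bounds map finitely
    scale = max(np.ptp(x), 1.0)

    def g1(k: float) -> float:
        return skew(np.log(x - k))

    hi_k = upper - 1e-9 * scale
    if g1(hi_k) > 0:
        raise ValueError("skewness still positive at the bracket end; "
                         "shift root not bracketed")
    lo_k = upper - scale
    for _ in range(60):
        if g1(lo_k) > 0:
            break
        lo_k = upper - 2 * (upper - lo_k)
    else:
        raise ValueError("failed to bracket the zero-skewness shift")
    k = brentq(g1, lo_k, hi_k, xtol=1e-12 * scale, rtol=8.9e-16)
    if abs(g1(k)) > SKEW_TOL:
        raise ValueError("zero-skewness root did not converge")
    return TransformSpec(shift=float(k), lo=lo, hi=hi,
                         lo_t=float(np.log(lo - k)),
                         hi_t=float(np.log(hi - k)))


def apply_transform(x: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Map raw values to the shifted-log scale, ln(x - k)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= spec.shift):
        raise ValueError("values at or below the shift cannot be transformed")
    return np.log(x - spec.shift)


def invert_transform(y: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Map transformed values back to the raw scale, exp(y) + k."""
    return np.exp(np.asarray(y, dtype=float)) + spec.shift
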