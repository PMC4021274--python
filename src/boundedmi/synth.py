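"""Synthetic GHQ-like data generator.

Emulates a 12-item mental-health screening questionnaire (items coded 0-3)
scored three ways — Likert (0-1-2-3, range 0-36), standard (0-0-1-1, range
0-12) and C-GHQ (0-0-1-1 for positively worded items, 0-1-1-1 for negatively
worded ones, range 0-12) — together with a correlated binary outcome
("living at home" at a later wave) and a correlated 4-level ordinal
auxiliary score from that later wave.

Items follow a single-factor ordinal probit model: person i has a standard
normal latent ``t_i``; the response to item j is the number of that item's
cutpoints lying below ``loading * t_i + e_ij`` with ``e_ij`` standard normal
item noise. The three built-in profiles are calibrated so the corresponding
score reproduces the qualitative skewness regimes of real GHQ data: weak
positive skew (Likert), moderate positive skew (C-GHQ) and a point mass at
zero with severe positive skew (standard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import AUX_LEVELS, CompleteDataset, as_rng

N_ITEMS = 12

#: Cutpoints used for the wave-9 auxiliary items in every profile: the
#: auxiliary is always the Likert-scored later-wave questionnaire, binned at
#: 0-5 / 6-8 / 9-11 / 12-36, whatever the scoring of the incomplete score.
_LIKERT_CUTS = (-0.5, 1.0, 2.2)
_AUX_BIN_EDGES = (6, 9, 12)


@dataclass(frozen=True)
class ItemTable:
    """n x 12 table of ordinal item responses in {0, 1, 2, 3}."""

    responses: np.ndarray
    negative_item_flags: np.ndarray
    person_latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses",
                           np.asarray(self.responses, dtype=int))
        object.__setattr__(self, "negative_item_flags",
                           np.asarray(self.negative_item_flags, dtype=bool))
        if self.responses.ndim != 2 or self.responses.shape[1] != N_ITEMS:
            raise ValueError(f"responses must have {N_ITEMS} columns")
        if self.responses.min() < 0 or self.responses.max() > 3:
            raise ValueError("item codes must lie in {0,1,2,3}")
        if self.negative_item_flags.shape != (N_ITEMS,):
            raise ValueError(f"need exactly {N_ITEMS} negative-item flags")
        if self.negative_item_flags.all() or not self.negative_item_flags.any():
            raise ValueError("need at least one negative and one positive item")

    @property
    def n(self) -> int:
        return self.responses.shape[0]


def _default_flags() -> np.ndarray:
    # which items are negatively worded is configurable; default: first six
    return np.arange(N_ITEMS) < 6


@dataclass(frozen=True)
class SynthProfile:
    """Parameters of the synthetic generator for one skewness regime.

    ``item_thresholds`` is a (12, 3) array of strictly increasing probit
    cutpoints per item; ``latent_loading`` scales the shared person latent
    relative to unit item noise (larger values give stronger inter-item
    correlation); ``latent_correlation`` links the wave-8 person latent to
    the wave-9 latent behind the auxiliary variable; the outcome is drawn
    Bernoulli(expit(outcome_intercept + outcome_slope * latent)).
    """

    name: str
    item_thresholds: np.ndarray
    latent_loading: float = 1.0
    latent_correlation: float = 0.5
    outcome_intercept: float = -1.0
    outcome_slope: float = 0.3
    zero_mass_target: float | None = None
    negative_item_flags: np.ndarray = field(default_factory=_default_flags)

    def __post_init__(self) -> None:
        thr = np.asarray(self.item_thresholds, dtype=float)
        if thr.shape == (3,):
            thr = np.tile(thr, (N_ITEMS, 1))
        if thr.shape != (N_ITEMS, 3):
            raise ValueError(f"item_thresholds must be ({N_ITEMS}, 3)")
        with np.errstate(invalid="ignore"):
            finite = np.isfinite(thr).all(axis=1)
        if np.any(np.diff(thr[finite], axis=1) <= 0):
            raise ValueError("cutpoints must be strictly increasing per item")
        object.__setattr__(self, "item_thresholds", thr)
        object.__setattr__(self, "negative_item_flags",
                           np.asarray(self.negative_item_flags, dtype=bool))
        if not 0.0 < self.latent_correlation <= 1.0:
            raise ValueError("latent_correlation must be in (0, 1]")


def likert_like() -> SynthProfile:
    """Mild positive skew on the Likert score (range 0-36)."""
    return SynthProfile(name="likert_like", item_thresholds=_LIKERT_CUTS)


def cghq_like() -> SynthProfile:
    """Moderate positive skew on the C-GHQ score (range 0-12)."""
    return SynthProfile(name="cghq_like", item_thresholds=(0.5, 1.8, 2.8))


def standard_like() -> SynthProfile:
    """Severe positive skew with a point mass at zero on the standard score.

    A high latent loading plus three "easy" and nine "hard" items
    concentrates zeros (about 30% of people endorse no item at the 0-0-1-1
    threshold) while the shared latent stretches a long right tail.
    """
    c2 = np.array([-0.53] * 3 + [4.47] * 9)
    thr = np.stack([c2 - 1.2, c2, c2 + 1.2], axis=1)
    return SynthProfile(name="standard_like", item_thresholds=thr,
                        latent_loading=2.5, zero_mass_target=0.30)


PROFILES = {
    "likert_like": likert_like,
    "cghq_like": cghq_like,
    "standard_like": standard_like,
}

#: Scoring method conventionally paired with each profile.
PROFILE_SCORING = {
    "likert_like": "likert",
    "cghq_like": "cghq",
    "standard_like": "standard",
}


def get_profile(name: str) -> SynthProfile:
    try:
        return PROFILES[name]()
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; "
                         f"choose from {sorted(PROFILES)}") from None


def _draw_items(latent: np.ndarray, thresholds: np.ndarray, loading: float,
                rng: np.random.Generator) -> np.ndarray:
    u = loading * latent[:, None] + rng.standard_normal((latent.size, N_ITEMS))
    with np.errstate(invalid="ignore"):
        return np.nansum(u[:, :, None] > thresholds[None, :, :], axis=2)


def generate_items(n: int, profile: SynthProfile,
                   seed: int | np.random.Generator | None = None) -> ItemTable:
    """Draw an n x 12 item table from the profile's latent ordinal model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    latent = rng.standard_normal(n)
    responses = _draw_items(latent, profile.item_thresholds,
                            profile.latent_loading, rng)
    return ItemTable(responses=responses,
                     negative_item_flags=profile.negative_item_flags,
                     person_latent=latent)


def score(items: ItemTable, method: str) -> np.ndarray:
    """Score an item table by one of the three conventions.

    likert: sum of raw codes (0-36); standard: number of items with code >= 2
    (0-12); cghq: code >= 2 for positively worded items, code >= 1 for
    negatively worded ones (0-12).
    """
    codes = items.responses
    neg = items.negative_item_flags
    if method == "likert":
        return codes.sum(axis=1).astype(float)
    if method == "standard":
        return (codes >= 2).sum(axis=1).astype(float)
    if method == "cghq":
        pos_part = (codes[:, ~neg] >= 2).sum(axis=1)
        neg_part = (codes[:, neg] >= 1).sum(axis=1)
        return (pos_part + neg_part).astype(float)
    raise ValueError(f"unknown scoring method {method!r}")


def score_bounds(method: str) -> tuple[float, float]:
    """Hard range limits implied by a scoring method."""
    return (0.0, 36.0) if method == "likert" else (0.0, 12.0)


def generate_auxiliary_and_outcome(
        items_latent: np.ndarray, profile: SynthProfile,
        seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the 4-level wave-9 auxiliary and the binary outcome.

    The auxiliary is produced by Likert-scoring a second item table whose
    person latent correlates ``latent_correlation`` with the wave-8 latent,
    then binning at 0-5 (low), 6-8 (moderate), 9-11 (high), 12-36
    (very high). The outcome is Bernoulli in the wave-8 latent.
    """
    rng = as_rng(seed)
    latent = np.asarray(items_latent, dtype=float)
    rho = profile.latent_correlation
    latent9 = rho * latent + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(latent.size)
    aux_items = _draw_items(latent9, np.tile(_LIKERT_CUTS, (N_ITEMS, 1)),
                            1.0, rng)
    likert9 = aux_items.sum(axis=1)
    aux = np.digitize(likert9, _AUX_BIN_EDGES)
    p = expit(profile.outcome_intercept + profile.outcome_slope * latent)
    outcome = (rng.random(latent.size) < p).astype(int)
    return aux, outcome


def make_dataset(n: int, profile: SynthProfile | str, method: str,
                 seed: int | np.random.Generator | None = None
                 ) -> CompleteDataset:
    """Generate a complete synthetic dataset: score, bounds, outcome, auxiliary."""
    if isinstance(profile, str):
        profile = get_profile(profile)
    rng = as_rng(seed)
    items = generate_items(n, profile, rng)
    s = score(items, method)
    aux, outcome = generate_auxiliary_and_outcome(items.person_latent,
                                                  profile, rng)
    lo, hi = score_bounds(method)
    return CompleteDataset(score=s, outcome=outcome, aux=aux, lo=lo, hi=hi)
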