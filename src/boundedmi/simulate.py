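"""Missingness-resampling simulation engine.

Fixes one complete dataset, computes its complete-data estimates Q_hat (and
complete-data variances U), then repeatedly (N replicates): imposes
missingness on the score, runs every imputation method on every requested
scale with m copies, analyses each copy, and pools with Rubin's rules.
Performance is summarised per method x scale x parameter as

* E[Qbar_m] and bias = E[Qbar_m] - Q_hat,
* E[Ubar_m] (to compare with U),
* Var(Qbar_m) across replicates against (1 + 1/m) E[B_m],
* coverage: the fraction of nominal 95% intervals containing Q_hat,

plus the average percentage of values imputed below/above the range limits
(recorded on the imputation scale, before rounding or back-transform).
Failed replicates (non-convergence, degenerate fits, separation) are
excluded per method with counts reported, never silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import PooledResult, analyze, rubin_pool
from .data import CompleteDataset
from .imputers import METHODS, CompletedSet, ImputationError, multiple_impute
from .missingness import MissingnessSpec, calibrate_alpha, impose
from .synth import PROFILE_SCORING, make_dataset

REPORT_COLUMNS = ["method", "scale", "parameter", "e_q_bar", "bias",
                  "e_u_bar", "var_q_bar", "between_est", "coverage",
                  "n_failed", "pct_below", "pct_above"]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: data profile, mechanism and method grid."""

    profile: str = "likert_like"
    scoring: str | None = None  # default: the profile's natural scoring
    mechanism: str = "MCAR"
    n: int = 714
    n_reps: int = 1000
    m: int = 20
    k: int = 5
    prop: float = 0.33
    methods: tuple[str, ...] = METHODS
    scales: tuple[str, ...] = ("raw",)
    parameters: tuple[str, ...] = ("marginal_mean", "log_odds_ratio")
    master_seed: int = 20140426
    matching: str = "type1"
    mcar_style: str = "fixed"

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if self.scoring is None:
            object.__setattr__(self, "scoring",
                               PROFILE_SCORING[self.profile])


@dataclass
class ScenarioResult:
    """Aggregated performance report plus run metadata."""

    config: ScenarioConfig
    q_hat: dict[str, float]
    u: dict[str, float]
    report: pd.DataFrame
    alpha: float | None
    n_reps_run: int
    failure_log: dict[tuple[str, str, str], int]

    def manifest(self) -> dict:
        return {
            "master_seed": self.config.master_seed,
            "n_reps": self.n_reps_run,
            "profile": self.config.profile,
            "scoring": self.config.scoring,
            "mechanism": self.config.mechanism,
            "alpha": self.alpha,
            "q_hat": self.q_hat,
            "u": self.u,
            "failures": {" / ".join(key): n
                         for key, n in self.failure_log.items() if n},
        }


def replicate_rng(master_seed: int, rep: int,
                  stream: int = 0) -> np.random.Generator:
    """Independent substream for replicate ``rep``.

    Stream 0 draws the missingness mask; stream 1 + j drives the j-th
    method x scale combination, so a single replicate (or a single method
    within it) can be rerun in isolation and reproduce its results exactly.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(rep, stream)))


def bias(e_q_bar: float, q_hat: float) -> float:
    """Signed bias E[Qbar_m] - Q_hat."""
    return e_q_bar - q_hat


def variance_checks(pooled: list[PooledResult], m: int
                    ) -> tuple[float, float, float]:
    """(E[Ubar_m], Var(Qbar_m), (1 + 1/m) E[B_m]) over replicates."""
    if len(pooled) < 2:
        raise ValueError("need at least 2 successful replicates")
    q_bars = np.array([p.q_bar for p in pooled])
    e_u_bar = float(np.mean([p.u_bar for p in pooled]))
    var_q_bar = float(np.var(q_bars, ddof=1))
    between_est = float((1.0 + 1.0 / m) * np.mean([p.b_m for p in pooled]))
    return e_u_bar, var_q_bar, between_est


def coverage(pooled: list[PooledResult], q_hat: float) -> float:
    """Fraction of pooled 95% intervals containing the complete-data
    estimate (closed interval)."""
    if not pooled:
        raise ValueError("need at least 1 successful replicate")
    return float(np.mean([p.covers(q_hat) for p in pooled]))


def pct_out_of_range(completed: list[CompletedSet]) -> tuple[float, float]:
    """Average percentage of imputed values below / above the limits,
    over copies and replicates, from pre-rounding counts."""
    below, above = [], []
    for cset in completed:
        if cset.n_imputed == 0:
            continue
        below.extend(100.0 * cset.n_below / cset.n_imputed)
        above.extend(100.0 * cset.n_above / cset.n_imputed)
    if not below:
        return math.nan, math.nan
    return float(np.mean(below)), float(np.mean(above))


def run_replicate(data: CompleteDataset, mspec: MissingnessSpec,
                  config: ScenarioConfig, rep: int):
    """Run one replicate: impose missingness, impute, analyse, pool.

    Returns ``{(method, scale): (pooled_by_parameter | None, cset | None,
    error_message | None)}``.
    """
    mask = impose(data, mspec, replicate_rng(config.master_seed, rep, 0)).mask
    out = {}
    combos = [(meth, sc) for sc in config.scales for meth in config.methods]
    for j, (method, scale) in enumerate(combos):
        rng = replicate_rng(config.master_seed, rep, 1 + j)
        try:
            cset = multiple_impute(data, mask, method, scale=scale,
                                   m=config.m, k=config.k, rng=rng,
                                   matching=config.matching)
            pooled = {}
            for param in config.parameters:
                per_copy = [analyze(y, data.outcome, param)
                            for y in cset.imputations]
                pooled[param] = rubin_pool(per_copy)
        except (ImputationError, ValueError) as exc:
            out[(method, scale)] = (None, None, str(exc))
        else:
            out[(method, scale)] = (pooled, cset, None)
    return out


def run_scenario(config: ScenarioConfig,
                 data: CompleteDataset | None = None) -> ScenarioResult:
    """Run the full missingness-resampling experiment for one scenario.

    The complete dataset is fixed once (generated from the profile with the
    master seed unless supplied); the MAR intercept is calibrated once on it
    before the replicate loop; every replicate then resamples only the
    missingness.
    """
    if data is None:
        data = make_dataset(config.n, config.profile, config.scoring,
                            seed=config.master_seed)
    mspec = MissingnessSpec(mechanism=config.mechanism, prop=config.prop,
                            mcar_style=config.mcar_style)
    if config.mechanism == "MAR":
        mspec = calibrate_alpha(data, mspec)

    q_hat, u = {}, {}
    for param in config.parameters:
        est = analyze(data.score, data.outcome, param)
        q_hat[param] = est.estimate
        u[param] = est.variance

    combos = [(meth, sc) for sc in config.scales for meth in config.methods]
    pooled_acc: dict = {c: {p: [] for p in config.parameters} for c in combos}
    pct_acc: dict = {c: ([], []) for c in combos}
    failures: dict = {c: 0 for c in combos}

    for rep in range(config.n_reps):
        rep_out = run_replicate(data, mspec, config, rep)
        for combo, (pooled, cset, err) in rep_out.items():
            if err is not None:
                failures[combo] += 1
                continue
            for param, pr in pooled.items():
                pooled_acc[combo][param].append(pr)
            if cset.n_imputed > 0:
                pct_acc[combo][0].extend(100.0 * cset.n_below / cset.n_imputed)
                pct_acc[combo][1].extend(100.0 * cset.n_above / cset.n_imputed)

    rows = []
    failure_log = {}
    for method, scale in combos:
        n_failed = failures[(method, scale)]
        below, above = pct_acc[(method, scale)]
        pct_b = float(np.mean(below)) if below else math.nan
        pct_a = float(np.mean(above)) if above else math.nan
        for param in config.parameters:
            pooled = pooled_acc[(method, scale)][param]
            failure_log[(method, scale, param)] = n_failed
            if len(pooled) < 2:
                rows.append({"method": method, "scale": scale,
                             "parameter": param, "e_q_bar": math.nan,
                             "bias": math.nan, "e_u_bar": math.nan,
                             "var_q_bar": math.nan, "between_est": math.nan,
                             "coverage": math.nan, "n_failed": n_failed,
                             "pct_below": pct_b, "pct_above": pct_a})
                continue
            e_q_bar = float(np.mean([p.q_bar for p in pooled]))
            e_u_bar, var_q_bar, between_est = variance_checks(pooled, config.m)
            rows.append({
                "method": method, "scale": scale, "parameter": param,
                "e_q_bar": e_q_bar, "bias": bias(e_q_bar, q_hat[param]),
                "e_u_bar": e_u_bar, "var_q_bar": var_q_bar,
                "between_est": between_est,
                "coverage": coverage(pooled, q_hat[param]),
                "n_failed": n_failed, "pct_below": pct_b, "pct_above": pct_a,
            })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ScenarioResult(config=config, q_hat=q_hat, u=u, report=report,
                          alpha=mspec.alpha, n_reps_run=config.n_reps,
                          failure_log=failure_log)
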