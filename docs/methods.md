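# Methods

## The evaluation design

The package benchmarks univariate multiple-imputation (MI) methods for a
bounded score using missingness resampling (Brand; van Buuren): one
complete dataset is fixed, its complete-data estimate `Q̂` and complete-data
variance `U` are treated as the reference, and N replicates each impose a
fresh missingness pattern on the score, impute it m times, analyse each
completed copy, and pool with Rubin's rules. Because `Q̂` is held fixed,
the design isolates the imputation machinery from complete-data sampling
variability: a well-calibrated ("proper") method should satisfy

* bias `E[Q̄m] − Q̂ ≈ 0`,
* `E[Ūm] ≈ U` (within-imputation variance unbiased for the complete-data
  variance),
* `Var(Q̄m) ≈ (1 + 1/m) E[Bm]` (between-imputation variance tracks the
  true replicate-to-replicate variability),
* ~95% coverage of `Q̂` by the interval
  `Q̄m ∓ √((1 + 1/m) Bm) · t_{m−1, 0.975}`.

The coverage interval deliberately uses only the between-imputation
component: with `Q̂` fixed, `Ūm` does not describe any variability of
`Q̄m − Q̂`, and including it would drive coverage to 1 for every method,
destroying the comparison. `rubin_pool` exposes the standard total-variance
interval (`interval="total"`) and the classic Rubin degrees of freedom
(`df="rubin"`) for real-data inference; the engine evaluates the
between-only, `t_{m−1}` construction.

Target parameters are the marginal mean of the score and the slope of a
univariable logistic regression of the fully observed binary outcome on the
score. Imputed scores are analysed as continuous values without re-rounding
to integers; "rounding" throughout means clamping to the range limits, not
rounding to whole numbers.

## Synthetic data generator

The generator emulates a 12-item screening questionnaire with items coded
0–3. Person i has a standard normal latent `t_i`; the response to item j is
the number of item-j cutpoints below `λ·t_i + e_ij`, with `e_ij` standard
normal item noise, `λ` a profile-level latent loading, and three strictly
increasing probit cutpoints per item. The shared latent induces realistic
inter-item correlation with few parameters. Three scoring rules map items
to scores: Likert (sum of codes, 0–36), standard (count of codes ≥ 2,
0–12) and C-GHQ (count of codes ≥ 2 for positively worded items plus codes
≥ 1 for negatively worded ones, 0–12). Which six items are "negatively
worded" is configurable; the default flags the first six.

The three built-in profiles were calibrated once, by Monte-Carlo scans over
cutpoints and loading, to land in the three qualitative skewness regimes
the analysis contrasts (large-sample moment skewness g₁ of the paired
score):

| profile | cutpoints | λ | g₁ band | achieved |
|---|---|---|---|---|
| `likert_like` | (−0.5, 1.0, 2.2) all items | 1.0 | 0.2–0.8 | ≈ 0.6 |
| `cghq_like` | (0.5, 1.8, 2.8) all items | 1.0 | 0.8–1.5 | ≈ 1.0 |
| `standard_like` | c₂ = −0.53 (3 items) / 4.47 (9 items), c₁ = c₂ − 1.2, c₃ = c₂ + 1.2 | 2.5 | > 1.5, P(0) ≈ 0.30 | ≈ 1.8, 0.30 |

The severe profile needs both the higher loading and heterogeneous
per-item thresholds: with a unit loading and exchangeable items, the
standard score's skewness at a fixed 30% zero mass peaks near 1.1, short of
the severe regime. Three "easy" items generate most of the non-zero mass
while the strong shared latent stretches the right tail.

The auxiliary variable is always the Likert-scored questionnaire at a later
wave — a second item table whose person latent correlates 0.5 with the
first-wave latent — binned at 0–5 (low), 6–8 (moderate), 9–11 (high),
12–36 (very high), regardless of how the incomplete score itself is
scored. The binary outcome ("living at home") is Bernoulli with logit
`−1.0 + 0.3·t_i` (prevalence ≈ 0.27, modest positive association with the
score). Default sample size n = 714.

What the generator does *not* emulate: the marginal distributions of any
particular cohort, item-level response wording effects, differential item
functioning, or missingness in the outcome/auxiliary. Passing tests show
the imputation machinery behaves correctly for data with these skewness
regimes and correlation structure, not that any substantive estimate from a
real cohort would be reproduced.

## Missingness

Only the score is ever masked. MCAR masks exactly `round(0.33·n)` scores by
simple random sampling without replacement (fixed count reduces pure
simulation noise; independent Bernoulli masking is available via
`mcar_style="bernoulli"`). MAR draws independent Bernoulli indicators with
`logit p_i = α + 1.25·Living_i + 0.2·1{aux=moderate} + 0.3·1{aux=high} +
0.4·1{aux=very_high}` — odds ratios 3.5, 1.22, 1.35 and 1.5. The intercept
α is calibrated once per dataset, before the replicate loop, by bracketed
root search so the mean of the `p_i` equals the target proportion (default
0.33) to within 10⁻⁶; the mean probability is continuous and strictly
increasing in α, so the root is unique.

## Imputation methods

All imputation models regress the score on an intercept, the binary
outcome, and three auxiliary indicators (moderate/high/very high vs low) —
indicators rather than a linear ordinal score, matching how the auxiliary
enters the missingness model. Every copy uses a fresh parameter draw, so
`Bm` reflects parameter uncertainty (proper MI).

* **regress**: σ*² = RSS/χ²_{n−p}, β* ~ N(β̂, σ*²(XᵀX)⁻¹), missing values
  filled with `x'β* + σ*·z`. Out-of-range values are retained.
* **regress_round**: the same copy, then imputed entries clamped to
  [lo, hi]. Out-of-range counts are recorded before clamping.
* **truncreg**: truncated-normal regression. The truncation model assigns
  probability only to `lo < y < hi`, so observations at or beyond the
  limits are excluded from the likelihood — the semantics of standard
  truncated-regression tools. This matters: including boundary observations
  makes the MLE diverge along the ridge toward the exponential limit
  (μ → −∞, σ → ∞) whenever the data carry a point mass at a bound, as the
  severe profile does. With strict truncation the fit is well-posed, and
  discarding the boundary mass is precisely why the method over-imputes on
  skewed scores. The likelihood is maximised in (β, ln σ) by L-BFGS-B with
  an analytic gradient from a least-squares start, inside a generous box
  (β within ±100·σ̂₀ of the OLS start, ln σ within ±4); `log(Φ(b) − Φ(a))`
  is computed from survival functions in the right tail to avoid
  cancellation. Parameter draws are multivariate normal around the MLE with
  the inverse observed information (central differences of the analytic
  gradient); imputations are inverse-CDF draws from the truncated normal,
  in-bounds by construction. Non-convergence or an indefinite information
  matrix marks the replicate failed for this method — reported, never
  silently replaced.
* **pmm**: type-1 predictive mean matching, k = 5 donors. Predicted means
  use β* for missing rows and β̂ for donors; each missing row takes the k
  observed rows with the smallest `|ŷ_mis − ŷ_obs|` (ties broken by an
  independent seeded shuffle per missing row — with indicator covariates
  many donors are exactly equidistant, and a shared tie-break order would
  correlate donations within a copy and inflate `Bm`), then donates a
  uniformly chosen candidate's observed value. Type-0 matching (β̂ for
  both) is available via `matching="type0"`.

## Zero-skewness transform

`fit_zero_skew` finds the shift k < min(x) with `g₁(ln(x − k)) = 0` to
within 10⁻⁶ by bracketed root search: the skewness of `ln(x − k)` tends to
the (positive) raw skewness as k → −∞ and to −∞ as k → min(x), so a sign
change always brackets the root; the biased moment coefficient
g₁ = m₃/m₂^{3/2} is used, the conventional criterion for this transform.
The transform is fitted to the *observed* values inside each replicate —
what an analyst with incomplete data can actually do. Bounds map to
`ln(lo − k)` and `ln(hi − k)` (finite because k < lo whenever the score
attains its lower bound); back-transformation is exact and never clips, so
extreme back-transformed imputations on severely skewed data are visible in
the results rather than hidden — that instability is itself a finding.

## Numerical and design choices

* Replicate r of a scenario uses seed substreams
  `SeedSequence(master_seed, spawn_key=(r, j))` — stream 0 for the mask,
  stream 1 + j for the j-th method×scale — so any single replicate or
  method can be rerun in isolation and reproduce its cells exactly.
* Degenerate inputs raise rather than impute: zero residual variance,
  rank-deficient design, constant score, logistic separation, truncated
  mass underflow (< 10⁻³⁰), too few interior observations.
* Failed replicates are excluded per method with counts in the report.
* MCAR fixed-count vs Bernoulli, PMM matching type, the interval and
  degrees-of-freedom conventions, and the per-replicate transform fit are
  all explicit options where the underlying convention is genuinely open.
* The acceptance run uses N = 1000 replicates at n = 714, m = 20 for the
  coverage quantities (Monte-Carlo SE of a 0.95 coverage proportion
  ≈ 0.007); the directional method-comparison suite uses N = 200, whose
  binomial Monte-Carlo error is still far smaller than the effects being
  ordered.

## Limitations

* Strictly univariate: one incomplete variable, complete covariates; no
  chained equations, joint multivariate-normal draws, or ordinal-logistic
  imputation.
* The truncated-regression draw uses the asymptotic-normal approximation
  around the MLE, not a full posterior; on near-pathological fits the
  approximation degrades exactly where the method already fails.
* The PMM donor-distance and tie-breaking rules follow the stated
  definition; other implementations differ in unpublished details, and PMM
  results are known to be sensitive to the matching variant.
* Conclusions from a missingness-resampling study are conditional on the
  fixed complete dataset; the generator's profiles are calibrated to skew
  regimes, not to any real cohort's margins.
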