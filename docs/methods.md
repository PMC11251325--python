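# Methods

## Model and parameters

A test-negative design (TND) study observes a care-seeking source
population of size `N` over a period `τ` (days). Every member who falls
ill with the target pathogen, or with a clinically similar test-negative
illness, seeks care and is tested; the study accumulates a 2×2 table of
vaccination (rows) by test result (columns) with cells `a, b, c, d`.
Vaccine effectiveness is `VE = 1 − OR` with `OR = ad/(bc)`.

Scenario parameters (`DesignParams`):

| parameter | meaning | default |
|---|---|---|
| `ve` | assumed vaccine effectiveness, in [0, 1] | — |
| `coverage` (`p_N`) | fraction vaccinated among test-negatives ≈ population coverage | — |
| `lambda_i` | hazard of test-positive illness, per day | 0.001 in the reference conditions |
| `lambda_n` | hazard of test-negative illness, per day | 0.002 |
| `tau` | study period, days | 100 |
| `pi` | percent positivity override (surveillance-based) | derived from hazards |
| `theta0` | null odds ratio of the one-sided test | 1 |
| `alpha` | one-sided significance level | 0.025 |
| `gamma` | 1 − target power | 0.2 |

With constant hazards, `Λ_I = λ_I τ` and `Λ_N = λ_N τ`. A scenario
supplies either the hazard triple or `pi` directly — never both; sizes
computed through either path agree whenever they imply the same `π`
(path independence, tested).

Derived quantities:

* `p_I = p_N(1−VE)/(1−p_N·VE)` — expected vaccinated fraction among
  positives. The implied odds ratio equals `1−VE` exactly, which is also
  the true log-OR used by the bias scan.
* `π = (1−p_N·VE)(1−e^{−Λ_I}) / [(1−p_N·VE)(1−e^{−Λ_I}) + Λ_N]` —
  expected positivity: the numerator is the per-capita expected number of
  positive tests (at most one per person), the `Λ_N` term the per-capita
  expected number of negative tests (recurrent).
* Score variance components
  `σ₀² = [πp_I+(1−π)p_N][π(1−p_I)+(1−π)(1−p_N)]/(π(1−π))` (null, pooled)
  and `σ₁² = p_I p_N(1−p_I)(1−p_N)/{π(1−π)[πp_I(1−p_I)+(1−π)p_N(1−p_N)]}`
  (alternative), from the simple logistic likelihood.
* Per-capita expected cells `u_a = p_N(1−VE)(1−e^{−Λ_I})`,
  `u_b = p_N Λ_N`, `u_c = (1−p_N)(1−e^{−Λ_I})`, `u_d = (1−p_N)Λ_N`; the
  simulator sizes the population as `N = ⌈n / Σu⌉` so that `n` tests are
  expected within one period.

## Hypothesis tests

All three tests are one-sided (`H₀: OR ≥ θ₀` vs `H₁: OR < θ₀`), rejecting
when the statistic falls below `z_α` (the α-quantile of the standard
normal, negative). A p-value (lower-tail normal) is reported alongside,
but the decision uses the statistic to avoid double rounding.

* **Wald**: `T_W = [ln(ad/bc) − ln θ₀]/√(1/a+1/b+1/c+1/d)`. Any zero
  cell is a defined intractable outcome (`tractable=False`), counted as a
  non-rejection in power summaries (conservative); an optional fallback
  mode re-tests intractable tables with the corrected statistic.
* **Corrected Wald**: every cell shifted by `δ > 0` (default Yates'
  `δ = 0.5`) in both the log-OR and its variance; always tractable, and
  converges to the Wald statistic as `δ → 0` on all-positive tables.
* **Score**: variance estimated under the null. At `θ₀ = 1` the closed
  form `T_S = (ad−bc)√n/√((a+c)(b+d)(a+b)(c+d))` is used. For general
  `θ₀`, the vaccination coefficient of a logistic model for
  P(vaccinated | test result) is fixed at `ln θ₀` and the intercept
  solved at its constrained maximum by bracketed root finding
  (`scipy.optimize.brentq`, tolerance 1e−10, 200 iterations, bracket
  ±500 on the logit scale — monotone, so a sign change is guaranteed for
  any table with positive margins); the statistic is the score divided by
  the square root of the profiled information
  `I₁₁ − I₁₀I₀₀⁻¹I₀₁`. The two paths agree at `θ₀ = 1` to 1e−8 (tested on
  random tables). Zero margins are intractable.

## Sample sizes

All calculators return `⌈·⌉` of the closed-form size — ceiling is the
rounding convention throughout, including the population size `N`;
intermediate quantities are never rounded, and the Fleiss-corrected size
is built from the **unrounded** Wald size (rounding first perturbs small
scenarios by ±1).

The TND-adjusted score size addresses the random positivity split: the
number of positives among `n` tests is Binomial(n, π), and the
unconditional power is

    Σ_{k=0}^{n} Φ( (z_α σ₀ − (p_I−p_N)√n) / σ̃₁(k/n) ) · C(n,k) π^k (1−π)^{n−k}

with `σ̃₁²(π̂) = p_I(1−p_I)/π̂ + p_N(1−p_N)/(1−π̂) + 2p_I p_N`, the
alternative variance under the multinomial distribution of the four
cells. `σ₀` is held at the design `π` (the pooled null variance is nearly
flat in `π̂`), while `σ̃₁` varies. The `k = 0` and `k = n` terms have a
divergent `σ̃₁` and describe single-column tables that cannot reject;
their rejection probability is set to 0 (their binomial mass is below
1e−9 at the sizes of interest). The size is found by a step-1 upward grid
search from the case-control score size; binomial weights come from
`scipy.stats.binom.pmf` (log-space internally, stable to n ≈ 10⁴) and are
verified to sum to 1 within 1e−12.

## Simulator

Per replicate: exact-count vaccination (`round(N·p_N)`, half-up) and
all-or-none protection (`round(n_vacc·VE)` of the vaccinated, half-up);
positive-test times exponential(λ_I) for the unprotected, kept if ≤ τ;
negative-test times are the first three arrivals of a rate-λ_N Poisson
process built from cumulative exponential gaps (exact construction) —
further negatives are disregarded, deflating `Λ_N` by under 1% in the
reference conditions, and positives do not remove individuals from
negative-test risk. The two illness processes are independent; each event
is a separate test.

Sampling rules:

* **TND**: pool all events, sort by time (floating-point ties broken by
  an independent uniform draw), keep the first `n`. If fewer than `n`
  events occur by `τ` the replicate keeps them all and is flagged
  `truncated` — with `N = ⌈n/Σu⌉` the expected event count is exactly
  `n`, so roughly half of replicates are a few tests short; the flag rate
  is reported on every summary.
* **Case-control**: the first `round(nπ)` positives by time plus a
  simple random sample of `n − round(nπ)` negatives. Replicates with too
  few events of either kind are redrawn with fresh randomness (the quota
  construction makes this common, ~2–3 redraws per accepted replicate;
  counts are logged).

Randomness: a single root seed spawns one `numpy` `SeedSequence` child
per replicate, so any replicate is reproducible in isolation and all
summaries are bit-reproducible given (scenario, seed, reps).

## Evaluation layer

`estimate_rejection_rate` reports the rejection proportion with binomial
Monte-Carlo SE; type-I mode regenerates data at the null boundary
`VE = 1 − θ₀` at the given `n` (the size is not recomputed). `zero_cell_frequency`
reports P(a = 0), the event that breaks the Wald test.
`continuity_scan` evaluates bias (against the true `ln(1−VE)`) and the
SD of the log-OR over a δ-grid in [0, 2]; δ = 0 entries are flagged NaN
whenever any replicate has a zero cell. The default replicate count is
100,000 (CLI), but validation runs use 10,000, where a two-decimal rate
carries a Monte-Carlo SE of ≤ 0.005.

## What the generator does and does not emulate

It reproduces passive accrual, the random positivity split, sparsity at
high VE, and the fixed-margin contrast with case-control sampling. It
does **not** model health-care-seeking differences by vaccination status,
imperfect test sensitivity/specificity, waning or leaky vaccines,
seasonality, time-varying coverage, or confounders — so passing tests
validate the design calculations under these idealized conditions, not
robustness of the TND to those real-world features.

## Known limitations and open points

* Under high VE with low coverage the normal approximation behind the
  TND-adjusted size is conservative: simulated power at the adjusted size
  exceeds the nominal target (e.g. ~0.86 at n = 228 for VE = 95%,
  coverage 10% versus the 0.80 design target).
* The score test's general-`θ₀` path assumes an interior constrained
  optimum; degenerate tables (zero margins) are reported intractable
  rather than approximated.
* `p_I` and `π` are large-population approximations; the simulator uses
  finite populations with exact-count assignment, so simulated moments
  match them only up to O(1/N) rounding effects.
* The multinomial alternative variance treats `p̂_I` and `p̂_N` as
  conditionally independent given `π̂`; the `+2p_I p_N` covariance term
  is the leading correction, not an exact finite-sample variance.
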