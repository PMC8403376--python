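# Methods notes

This note records the modelling conventions, numerical choices and
deliberate design decisions behind `itseval`, in the spirit of the
methods documentation that simulation-heavy statistical packages ship.

## The model and its estimands

The package fits the Huitema–McKean segmented linear regression for a
single-interruption ITS,

    Y_t = β₀ + β₁ t + β₂ D_t + β₃ (t − T_I) D_t + ε_t,    t = 1, …, N,

with `D_t = 1(t ≥ T_I)`. **Time-index convention** (this fixes the
meaning of β₂ and is worth stating twice): `T_I` is the *first
post-interruption time point*, so the slope-change regressor is zero at
`t = T_I` and the fitted level change is the jump between the projected
pre-trend and the post segment at that point. A "midpoint" interruption
on an even-length series is `T_I = N/2 + 1`: exactly N/2 points on each
side. No centering or rescaling of `t` is applied anywhere, because the
estimand definitions depend on this parameterisation.

Errors are stationary Gaussian AR(1): `ε_t = ρ ε_{t−1} + w_t`,
`w_t ~ N(0, σ²)`, `|ρ| < 1`. The estimands tracked by the Monte-Carlo
machinery are β₂ (level change), β₃ (slope change), ρ, and the
Durbin-Watson statistic.

## Data generation

* **Stationary start.** The first error is `w_1 · sqrt(1/(1−ρ²))`, so
  every error has marginal variance σ²/(1−ρ²) and the lag-k
  autocorrelation is ρᵏ at all time points. This removes any transient
  and makes burn-in unnecessary.
* **Seeding.** Repetition `r` of scenario `s` under master seed `m`
  draws from `SeedSequence(m, spawn_key=(s, r))`. Substreams are
  statistically independent by construction, results are bit-identical
  regardless of execution order or parallelism, and each repetition's
  stream identity is recorded in the experiment manifest. This replaces
  the older practice of burning a fixed number of draws between
  consecutive data sets; substreams give stronger independence
  guarantees and trivially reproducible per-repetition streams.
* **Study grid.** The default factorial grid crosses level changes
  {0, 0.5, 1, 2} × slope changes {0, 0.1} × ρ {0, 0.2, 0.4, 0.6, 0.8} ×
  N {6, 8, …, 20, 24, 28, …, 56, 60, 80, 100}, with β₀ = β₁ = 0 and
  σ² = 1 — 800 scenarios. These values mirror the distribution of
  standardised effect sizes, autocorrelations and series lengths
  observed in published public-health ITS studies, so the operating
  characteristics computed on the grid speak to realistic practice.
  The generator accepts arbitrary β₀, β₁, σ² for reuse beyond the grid.

The generator emulates the *error structure and design geometry* of
real ITS data, not everything about it: errors are Gaussian,
homoskedastic and lag-1 only; segments are equal length; observations
are equally spaced with no missingness, seasonality, counts/rates
link functions, or interruption-phase-in. Passing tests therefore
certify behaviour under the AR(1) Gaussian model, and say nothing about
robustness to, e.g., seasonal confounding or heavy-tailed noise.

## Estimation methods

All methods return the same contract (coefficients, model-based SEs,
per-coefficient t degrees of freedom, ρ̂, innovation-variance estimate,
convergence flag, raw residuals). `sigma2` is always the innovation
(white-noise) variance for the AR-aware methods and the residual
variance for OLS/NW; the marginal error variance is `sigma2/(1−ρ̂²)`.

* **OLS.** Closed form; df = N−4. Coefficients are unbiased under
  autocorrelation but the SEs assume independence.
* **Newey-West.** OLS coefficients; Bartlett-kernel sandwich with
  weight `w_ℓ = 1 − ℓ/(L+1)` (lag L = 1 by default, so w₁ = 1/2) and
  small-sample factor N/(N−4) — the common econometric correction,
  matching HAC with `use_correction` in standard libraries. Lag 0
  reduces to an HC1-type sandwich.
* **Prais-Winsten.** Iterated feasible GLS. ρ̂ is the residual lag-1
  autocovariance ratio `Σ e_t e_{t−1} / Σ e_t²` (default; the
  lagged-regression slope variant is selectable and differs at
  O(1/N)). The quasi-difference transform keeps a
  `sqrt(1−ρ̂²)`-scaled first row — this is exact whitening of the AR(1)
  covariance, so a one-shot GLS at the converged ρ̂ reproduces the fit
  exactly. Convergence: |Δρ̂| < 1e-6, at most 100 iterations;
  oscillation (a return to any of the previous four iterates) and
  |ρ̂| ≥ 1 are counted as non-convergence and flagged, never raised.
  With the autocovariance-ratio estimator |ρ̂| < 1 always holds
  (Cauchy–Schwarz), so failures are rare even at N = 6. A numerically
  perfect fit (residual SS below 1e-24 of the outcome scale) is treated
  as ρ̂ = 0, which makes the method collapse to OLS on noiseless data
  instead of chasing float noise. Cochrane-Orcutt (drops the first
  observation, df = N−5) is provided as an opt-in variant only.
* **REML.** Parameterised as `y ~ N(Xβ, σ²_m V(ρ))`, `V_ij = ρ^{|i−j|}`.
  The restricted log-likelihood is profiled over β (GLS) and σ²_m and
  maximised over ρ by bounded Brent search on (−0.999, 0.999) with
  xatol 1e-6. All V(ρ) algebra uses the closed forms via the
  Prais-Winsten transform (`T V T' = (1−ρ²) I`,
  `|V| = (1−ρ²)^{N−1}`); a literal dense-matrix implementation is kept
  in the test suite as the oracle. An optimum within 1e-3 of the ρ
  boundary, or an optimizer failure, is declared non-convergence — this
  deterministic rule reproduces the characteristic failure rate of
  iterative REML software on very short series (about 30% at N = 10 in
  this package's own measurements). Unadjusted REML uses df = N−4.
* **Satterthwaite df.** For contrast c: ν = 2ψ²/(gᵀI⁻¹g) with
  ψ = σ²_m [(XᵀV⁻¹X)⁻¹]_cc, g its gradient in (ρ, σ²_m) (central
  differences, relative step 1e-4 — step-halving changes ν by < 0.1%)
  and I the observed information of the restricted likelihood
  (finite-difference Hessian). ν is floored at 2 to avoid nonsensical
  intervals, and a singular information matrix returns the floor with a
  flag. With ρ treated as known the formula collapses to ν = N−4
  analytically, which the tests verify numerically.
* **ARIMA (exact-ML ARMAX).** Same V(ρ) likelihood with divisor N in
  the profiled variance and no restricted term. ρ̂ by bounded profile
  search; coefficient SEs from the inverse finite-difference Hessian of
  the joint negative log-likelihood over (β, ρ, σ²_m) at the optimum, so
  the uncertainty of ρ̂ is inside the SEs (unlike PW). A non-positive-
  definite Hessian or boundary optimum flags non-convergence.
  Interval reference: t(N−4) by default; the normal reference (common
  in time-series software) is selectable. The df choice for ARIMA and
  NW intervals is a genuine convention gap in the field; both are
  exposed as options rather than hard-coded.

## Durbin-Watson test

Bounds d_L, d_U are computed from the eigenvalues
`λ_i = 2(1 − cos(πi/n))` of the first-difference quadratic form — the
smallest and largest n−k subsets respectively, k = 4 parameters
including the intercept — by Imhof inversion of the characteristic
function and Brent root-finding on the tail probability. This works at
any n ≥ 6 (published tables are sparse there) and matches the published
5% Savin-White values to the printed two decimals at n = 20, 50, 100;
a large-sample Monte-Carlo quantile check agrees to ~3 decimals.

Classification applies the bounds symmetrically: d < d_L → positive,
d > 4−d_L → negative, d within [d_U, 4−d_U] → none, else inconclusive.
**Tail-level convention:** by default the bounds are evaluated at the
stated significance level (0.05) in *each direction*, because that is
how the classical 5% bounds tables are used in practice and it is the
convention that reproduces published ITS method-evaluation operating
characteristics (≈30% inconclusive / 63% none / 7% positive at N = 48,
ρ = 0.2; ≈26% positive at N = 24, ρ = 0.8). A strict overall-α
two-sided split (α/2 per tail) is available via `split_alpha=True`; it
shrinks the rejection regions and roughly halves the detection rates.
The positive-tail size is conservative by construction (≤ α for every
design), which the suite checks empirically at ρ = 0.

## Performance measures

Morris–White–Crowther conventions: bias = mean − truth
(MCSE empSE/√n); empirical SE = SD with n−1 divisor
(MCSE sd/√(2(n−1))); model SE = √mean(SE²); coverage and power as
binomial proportions of CIs containing truth / excluding zero with
√(p(1−p)/n) MCSEs. 10,000 repetitions keep all proportion MCSEs below
0.5 percentage points. Non-converged repetitions are excluded from
numerator *and* denominator by default and reported as a separate
convergence fraction; the `denominator="all"` option instead counts
them as non-covering, since the literature is not explicit about the
convention. Power is flagged "approximate" whenever the same method's
coverage in the scenario falls below 90%: power read off a badly
calibrated interval is not comparable across methods.

## Problem sizes

The shipped test-suite and acceptance runs are sized for a single CPU:
10,000 repetitions for the Durbin-Watson, convergence and calibration
checks (matching the design MCSE of the full study), 5,000 for the
per-method unbiasedness grid (ρ ∈ {0, 0.4, 0.8} × N ∈ {12, 48, 100}),
and 1,000–2,000 for the ρ̂-bias orderings, which are coarse qualitative
contrasts. The full 800 × 10,000 × 6 experiment is supported through
`run_experiment`/`its-simulate` with per-scenario checkpointing and
scenario-level parallelism; it is a cluster-scale job and is not part
of the default configuration.

## Known limitations

Single series, single interruption, equal segments, lag-1 Gaussian
errors with constant variance — by design, matching the scope of the
evaluation the package implements. No Kenward-Roger or robust/Bayesian
variants; no Breusch-Godfrey/Ljung-Box alternatives to Durbin-Watson;
no calendar-time regression in `fit_dataset` (input times are mapped to
t = 1..N in observation order). REML non-convergence is defined by the
boundary rule above; other software draws the failure line differently,
so convergence *rates* are comparable only qualitatively across
implementations.
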