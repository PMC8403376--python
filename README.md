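# itseval

Segmented-regression analysis of interrupted time series (ITS) with
lag-1 autoregressive errors, and a Monte-Carlo engine for evaluating how
well the common estimation methods actually perform on such data.

ITS designs are a workhorse of policy and public-health evaluation: an
outcome is observed at regular intervals before and after an
interruption (a policy change, an exposure, an intervention), and the
pre-interruption trend provides the counterfactual for the post period.
The standard analysis is the segmented linear model

```
Y_t = β₀ + β₁·t + β₂·D_t + β₃·(t − T_I)·D_t + ε_t ,   t = 1, …, N
ε_t = ρ·ε_{t−1} + w_t ,   w_t ~ N(0, σ²)
```

where `D_t = 1(t ≥ T_I)` marks the post-interruption segment, `β₂` is the
immediate **level change**, `β₃` the **slope change**, and the errors are a
stationary AR(1) process with lag-1 autocorrelation `ρ`. Serial
correlation is the central nuisance: ignoring positive `ρ` makes
standard errors spuriously small, while estimating it from short series
is hard enough that the "corrected" methods can do worse than ignoring
it. This package exists to quantify exactly that trade-off.

## What's inside

* **Model objects** (`SegmentedITS` → `ITSResults`): six fitting
  procedures sharing one result contract — OLS; Newey-West (Bartlett
  kernel) HAC standard errors; iterated Prais-Winsten feasible GLS;
  REML for the AR(1) covariance, with optional Satterthwaite degrees of
  freedom (floored at 2); and exact-ML regression with AR(1) errors
  ("ARIMA"), whose SEs come from the joint observed information so
  autocorrelation uncertainty propagates into the coefficient SEs.
  A Cochrane-Orcutt variant is available but not part of the default set.
* **Durbin-Watson bounds test** (`dwtest`): the d statistic, exact
  lower/upper critical bounds at any series length via Imhof inversion
  of the quadratic-form characteristic function (no scanned tables),
  and the four-way positive / negative / none / inconclusive
  classification.
* **Simulation engine** (`simulate`, `runner`): stationary AR(1) series
  generation with per-(scenario, repetition) random substreams, the
  800-cell factorial study grid, and a config-driven experiment runner
  with per-scenario checkpointing.
* **Performance measures** (`performance`): bias, empirical SE,
  model-based SE and their ratio, coverage, power and convergence
  fractions — each with its Monte-Carlo standard error.

## Worked example

```python
import numpy as np
from itseval import (ITSDesign, ModelParams, SegmentedITS, SimulationConfig,
                     simulate_series, dw_test)

params = ModelParams(beta0=10.0, beta2=-2.0, beta3=-0.1, rho=0.4, sigma2=1.0)
design = ITSDesign.midpoint(48)           # interruption at t = 25
rng = SimulationConfig(1, master_seed=42).rng(0, 0)
series = simulate_series(params, design, rng)

model = SegmentedITS.from_series(series)
print(model.fit("REML", satterthwaite=True).summary())
dw = dw_test(model.fit_ols().resid)
print(f"DW d = {dw.statistic:.2f} (dL = {dw.d_lower:.2f}, "
      f"dU = {dw.d_upper:.2f}) -> {dw.classification}")
```

prints

```
Segmented ITS regression — method: REML-Satt
N = 48, interruption at t = 25
rho_hat = 0.2690  sigma2_hat = 1.3717  converged = True
------------------------------------------------------------------------
                    coef        se      df       t    P>|t|   [CI low  CI high]
     intercept    9.8664    0.6488     8.9   15.21   0.0000    8.3955   11.3372
     pre_slope    0.0662    0.0449     9.7    1.47   0.1721   -0.0343    0.1667
  level_change   -3.0309    0.8534    12.9   -3.55   0.0036   -4.8765   -1.1853
  slope_change   -0.1957    0.0651     8.1   -3.00   0.0167   -0.3455   -0.0458

DW d = 1.66 (dL = 1.41, dU = 1.67) -> inconclusive
```

The level change is estimated at −3.03 (true value −2, within its CI),
REML recovers ρ̂ = 0.27 from the true 0.4 — autocorrelation is typically
underestimated at this length — and the Satterthwaite degrees of
freedom (8–13, versus the naive N−4 = 44) widen the intervals to
account for the estimated covariance. The DW statistic of 1.66 falls
in the inconclusive region even though ρ = 0.4 generated the data: a
concrete illustration of why two-stage "test, then choose a method"
strategies fail on series of this length.

Command-line wrappers exist for the three everyday tasks:
`its-fit data.csv --interruption 11` (multi-method reanalysis of one
dataset), `its-dw data.csv --interruption 11` (Durbin-Watson test) and
`its-simulate --config cfg.yaml --out results/` (factorial experiment).

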