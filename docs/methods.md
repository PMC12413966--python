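# Methods

## Structural model and assumptions

The disposition model is the standard mammillary two-compartment model for
an IV antibody: central volume `vc` (sampled), peripheral volume `vp`,
distributional clearance `q`, linear elimination clearance `cl` from the
central compartment, and an optional parallel Michaelis–Menten pathway
(`vm`, `km`). Everything is expressed per kg of body weight (mL/kg,
mL/day/kg, µg/mL, days); mg/kg doses are converted ×1000 at public
boundaries. Assumptions baked in: drug enters only the central compartment
(IV bolus or zero-order infusion), elimination only from the central
compartment, no absorption or covariate sub-models, no target-mediated
disposition beyond the single Michaelis–Menten term.

Doses are treated as instantaneous boluses by default. Infusions are
supported (closed-form and analytic AUC included) but nothing turns them on
implicitly; the reported multiple-dose exposures assume boluses.

For `vm = 0` the model is linear; profiles are evaluated with the
closed-form biexponential (superposition over doses) and AUC is integrated
term by term, exactly. `AUC(0,∞) = Σdoses/cl` is an identity of this
implementation and is tested at 1e-8 relative. With `vm > 0` the amounts
ODE is integrated with LSODA at `rtol = 1e-8`, `atol = 1e-10`, restarting
at every dose boundary so bolus jumps are exact. A concentration requested
exactly at a dose instant reports the post-dose value (`C(0⁺) = D/vc`).

`cl = 0` is admitted as a diagnostic limit (it enables a pure
redistribution test of mass conservation); operations that require
elimination — terminal half-life, AUC to infinity — reject it explicitly.

## Estimation

**Pooled fit.** All subjects' observations are fitted jointly (naive
pooling) by minimizing the extended-least-squares objective

    OFV(θ) = Σ_j [ (dv_j − f_j(θ))² / g_j² + ln g_j² ],   g = a + b·f,

which is −2·log-likelihood of independent normal residuals up to a
constant. Defaults follow the study protocol: initials Vc=Vp=40, CL=5,
Q=10; bounds Vc,Vp ∈ [10, 200], CL ∈ [1, 30], Q ∈ [1, 100]; Vm=0 and Km=5
held fixed. Optimization runs on the log-parameter scale under box bounds
(L-BFGS-B) from five deterministic start points (the initials scaled by
fixed ±20% patterns); the best optimum is kept, which makes the fit fully
reproducible without a global optimizer. Standard errors come from the
inverse central-difference Hessian of OFV/2 at the optimum (relative step
1e-4), with NaN reported where the Hessian is not positive definite.

Two properties of this estimator are worth knowing and are frozen in the
test suite rather than hidden:

* *The ELS offset.* Because `g` depends on the prediction, the `ln g²` term
  rewards slightly smaller predictions: on noise-free data the optimum sits
  ≈ `b²` (1% at `b = 0.1`) below the observations, so volume and clearance
  estimates land ≈ +1% of the generating values, and a fully closed loop
  (generate → fit → MAP → metrics, no noise, no variability) yields
  AFE ≈ 0.99 rather than exactly 1.
* *CL attenuation under inter-subject variability.* Naive pooling of
  subjects whose CL is log-normal with 30% CV fits one curve through a
  mixture of decay rates; late-time mixture concentrations are dominated by
  slow eliminators, the pooled terminal slope flattens, and the pooled CL
  estimate falls systematically below the typical value (tens of percent at
  30% CV; the suite freezes the band (−30%, +5%) at a 60-subject design).
  With residual noise only (no IIV) the fit recovers CL within a few
  percent at 6 subjects and under 2% at 60. Recovery claims for this
  pipeline should therefore be read against the no-IIV case; a pooled fit
  is not an unbiased estimator of the typical value under strong IIV.

**MAP-Bayes.** Per subject, the population model acts as a log-normal
prior: `P_i = TV·exp(η)`, `η ~ N(0, ω²)` per estimated parameter, and

    OFV_MAP(η) = Σ_j [ (dv_j − f_j(η))²/g_j² + ln g_j² ] + Σ_P η_P²/ω_P².

Minimization starts at the prior mode `η = 0` (returned exactly when a
subject has no observations). `ω²` is not estimated from data; it defaults
to 0.09 per parameter (30% CV) and is configurable. Shrinkage behaves as
expected: `|η̂|` is non-increasing in the residual SD, and `ω² = 0` pins a
parameter to its typical value. `η` for `q` is the weakly identified one —
its estimate carries most of the sampling noise unless the distribution
phase (α half-life ≈ 0.27 d at the reference parameters) is sampled.

Convergence tolerances: objective `ftol 1e-10`, gradient `gtol 1e-8`,
tighter than any tolerance asserted downstream.

## Monte-Carlo simulation, VPC and projection

Individuals are drawn as `P_i = TV·exp(η_i)` with independent
`η_i ~ N(0, ω²)` per parameter (fixed parameters copied); a single
`numpy` Generator seeded by the caller makes every stochastic stage
bit-reproducible. Residual noise, when requested, is added per point as
`N(0, (a + b·IPRED)²)` with negative results truncated to 0 (simple,
documented, negligible at the default noise level). Prediction intervals
are pointwise linear-interpolation empirical quantiles (numpy's default),
stated explicitly because bit-reproducibility of the ribbons depends on the
quantile definition. A self-consistency check holds by construction:
~90% of points simulated under the model fall inside the 5–95% ribbon of a
1000-subject simulation (tested against the band [0.86, 0.94]).

The VPC evaluates the simulation exactly at the observed time points — no
time-binning — because the emulated study is sparse (six subjects on a
shared schedule); observations are dose-normalized to the reference dose
(10 mg/kg) by linear scaling, which is exact for the linear model.

Scenario projection (e.g. 10 mg/kg weekly ×4 over 28 days) uses the typical,
zero-variability profile with clearance scaled by the scenario multiplier,
and reports analytic AUC(0–28); the 0.5× multiplier row is the
half-clearance sensitivity case. The projection is deliberately *not* a
population mean: the scenario fixes a single clearance value.

## Synthetic study generator

The generator emulates the kind of dataset the analysis expects: six
subjects, three at 10 mg/kg and three at 100 mg/kg, single IV bolus at
t = 0, a shared sampling schedule (0.25, 1, 3, 7, 14, 21, 28 days — chosen
to span the biexponential decay over 28 days; the real study's schedule is
not published, so this is explicit and configurable), log-normal IIV
(default 30% CV) and combined residual noise. Non-positive noisy values are
floored at the additive SD (1e-6 when the additive term is zero). Each
subject has an RNG stream keyed by (seed, subject index), so changing group
composition does not perturb other subjects, and a sidecar table records
every η and individual parameter, making each DV replayable from the seed.

What it does **not** emulate: assay LLOQ/censoring, covariates, dropout,
irregular per-subject schedules, infusion administration, and any model
misspecification. Passing tests on generated data therefore demonstrate
self-consistency of the pipeline under its own assumptions — not accuracy
on real clinical data, where those features exist.

## Numerical choices

* Hybrid rates: `β` from the Vieta product `αβ = k10·k21` (stable for small
  discriminants); when `(α−β)²/(α+β)² < 1e-12` the closed form is abandoned
  for the ODE path (macro-coefficients suffer catastrophic cancellation).
* `q = 0` degenerates cleanly to one compartment (the β mode has zero
  coefficient); terminal half-life then uses `k10`, the observable rate.
* Numeric AUC: dense grid of 2000 points per 28 days, trapezoid rule, with
  each bolus instant bracketed by a pre-dose point (the profile jumps
  there; a one-sided point biases the integral by ~h·D/(2vc) per dose).
  Default-grid numeric AUC agrees with the analytic integral to 0.1%.
* Multi-start tie-break: the best objective wins; ties keep the earliest
  start (deterministic order).
* CSV round-trip: floats are serialized with `repr`, so write→read is
  bit-exact; missing DV/AMT cells are written as `"."` in the NONMEM style.

## Problem sizes

The test-suite and pipeline defaults use the study-scale conditions: 6
subjects (42 observations) for fitting, 1000 simulated subjects for VPC
ribbons and density summaries, 400 subjects for coverage validation, and
60 subjects where estimator consistency is examined. These sizes are the
package's chosen defaults; all are configurable.

## Known limitations

* No population (FOCE/SAEM) estimation of ω² — the IIV variance is an
  input, not an estimate; no covariance step beyond the numerical Hessian.
* Naive pooled fitting is biased under strong IIV (see above); it is kept
  because it is the estimator this analysis is built around.
* PE is defined as `100·(pred−obs)/obs` (so negative MPE means average
  under-prediction) and metrics default to individual (MAP) predictions,
  with a flag for population predictions; both conventions are stated
  because the fold-error literature varies.
* Acceptance band endpoints (0.8, 1.25) are inclusive.
* Only CMT=1 (central) dosing/observation records are supported; no BLQ
  handling, steady-state records, or interoccasion variability.
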