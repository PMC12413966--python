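# poppk

Population pharmacokinetics of an intravenously dosed antibody with a
two-compartment disposition model: naive-pooled parameter estimation,
MAP-Bayesian individual estimation, Monte-Carlo visual predictive checks
(VPC), dosing-regimen projection and fold-error predictive-performance
metrics — plus a seeded synthetic study generator so the whole analysis can
be exercised end to end without access to the original clinical dataset.

It is written for pharmacometricians and modelers who want a scriptable,
reproducible pipeline (library + CLI) rather than an interactive tool.

## The model

Drug amounts in a central compartment (volume `Vc`, the sampled one) and a
peripheral compartment (`Vp`) exchange through the distributional clearance
`Q`, with linear elimination clearance `CL` from the central compartment and
an optional parallel Michaelis–Menten term (`Vm`, `Km`):

    Vc·dC1/dt = −CL·C1 − Q·C1 + Q·C2 − Vm·C1/(Km + C1) + input
    Vp·dC2/dt =  Q·C1 − Q·C2

Units are per-kg throughout: mL/kg, mL/day/kg, µg/mL, days; doses in mg/kg
are converted (×1000) to µg/kg at the boundary. For `Vm = 0` the model is
linear and an IV bolus `D` gives the closed-form biexponential

    C(t) = (D/Vc)·[ (α−k21)/(α−β)·e^(−αt) + (k21−β)/(α−β)·e^(−βt) ],

with `k10 = CL/Vc`, `k12 = Q/Vc`, `k21 = Q/Vp` and `α ≥ β` the roots of
`x² − (k10+k12+k21)x + k10·k21`. Multi-dose profiles follow by superposition
and AUC is integrated analytically; nonlinear elimination falls back to a
stiff-capable ODE integrator.

Estimation minimizes the extended-least-squares objective
`Σ[(DV−f)²/g² + ln g²]` with the combined residual SD `g = a + b·f`
(defaults `a = 0.01` µg/mL, `b = 0.1`). Individual (MAP) estimation adds the
log-normal prior penalty `Σ η²/ω²` with `P_i = TV·exp(η)`. Predictive
performance is summarized by MPE (mean of `100·(pred−obs)/obs`),
`AFE = 10^mean(log10(pred/obs))` and `AAFE = 10^mean(|log10(pred/obs)|)`,
checked against the conventional 0.8–1.25-fold acceptance band.

## Worked example

Write a minimal config and run the full pipeline (all stages also exist as
separate subcommands: `synth`, `fit`, `map`, `vpc`, `project`, `metrics`):

```yaml
# demo.yaml
dataset: synthetic
simulation: {n: 1000, reference_dose: 10.0}
seed: 20240601
out: demo_run
```

```sh
poppk run-all --config demo.yaml
```

This generates a six-subject single-dose study (three subjects at 10 mg/kg,
three at 100 mg/kg, 30% CV log-normal inter-subject variability around the
reference parameters CL=7.02, Q=50.55 mL/day/kg, Vc=49.86, Vp=33.14 mL/kg),
fits it, and writes the analysis artifacts. With the seed above,
`fit_report.csv` reads:

```
parameter,initial,estimate,se,unit
vc,40.0,54.81,4.80,mL/kg
vp,40.0,27.97,4.95,mL/kg
cl,5.0,6.888,0.112,mL/day/kg
q,10.0,31.42,13.52,mL/day/kg
```

i.e. the pooled fit recovers the generating clearance to ~2% on this
realization (CL is well identified; Q is the weakly identified parameter,
visible in its large standard error). `scenario_summary.csv` projects a
10 mg/kg weekly ×4 IV regimen from the fitted parameters:

```
cl_multiplier,cl,auc_0_28,terminal_halflife
1.0,6.888,4148.83,8.55
0.5,3.444,5735.02,16.88
```

AUC(0–28) rises by ~38% (not 2×) when clearance is halved because part of
the exposure gain falls beyond day 28. `metrics.csv` compares observations
with the MAP individual predictions:

```
afe,aafe,mpe,n,band_pass
1.004,1.079,0.93,42,True
```

AFE ≈ 1 (no systematic fold bias), AAFE ≈ 1.08 (typical prediction within
8%), MPE ≈ +0.9% — comfortably inside the 0.8–1.25 acceptance band.
`vpc.csv` holds the 5th/50th/95th percentile ribbons of 1000 simulated
subjects at the 10 mg/kg reference dose with `vpc_observed.csv` the
dose-normalized observations overlaid on them.

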