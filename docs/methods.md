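# Methods

## Model structure and assumptions

The twin is a deterministic 12-state ODE system driven by
piecewise-constant drink inputs and instantaneous meal events.

**Units.** Time min; stomach/blood volumes dL; ethanol concentrations
mg/dL; ethanol masses mg; energy kcal; PEth ng/mL. Drink volumes are
specified in L — the explicit ·10 factors in the stomach-volume and
drink-inflow equations are the L→dL conversion. The factor
789.1 mg/dL per v/v% converts beverage strength to an ethanol
concentration (ethanol density 0.7891 g/mL); meal calories convert to
volume at 4 kcal/g and density 1 g/mL.

**Gastric emptying.** Liquid emptying is a Michaelis–Menten function of
the volume in excess of a residual 0.001 dL, multiplied by
`exp(−Kcal_Liquid/kKcal)`: the total liquid caloric load, not its
density or type, slows emptying. Liquid calories decay with their own
first-order clearance and do not leave with the emptied volume. Solid
(meal) calories follow the Tougas power-exponential retention curve;
its flux form is implemented with the printed coefficient/exponent pair
(1.88, 0.86) rather than the analytic derivative of the retention curve
(which would reuse the shape exponent 1.86). Both constants live in
`ModelConstants`, so the analytic-derivative convention is one field
away; the default reproduces the published dynamics.

**Bookkeeping states.** `time_elapsed` (minutes since the last meal)
integrates with rate 1 and is reset to 0 by meal events;
`max_kcal_solid` has zero derivative and changes only at events. Both
are listed as states because the solid-emptying flux needs them
continuously.

**Meal effect (food pool).** Ethanol diffuses into the solid phase down
the gradient between the stomach concentration and the pool's own
concentration (pool mass over the meal's remaining volume), and leaks
back first-order. The exchange is hard-gated to zero when
`kcal_solid ≤ 1` kcal or the stomach volume is below twice the residual
volume — no smoothing of the `max(·)` kinks; the stiff solver handles
them. A consequence worth knowing: once the liquid has emptied, the
gate closes and whatever ethanol is still encapsulated is frozen until
digestion completes, at which point the reset discards it. For a
spirit-with-700-kcal-meal scenario this discards roughly 40% of the
dose; this loss, not a slower absorption alone, is what reproduces the
strongly blunted fed-state BAC data.

**Digestion reset.** The reset fires when `kcal_solid` crosses 1 kcal
from above (located by the solver's root-finding), zeroing
`kcal_solid`, `max_kcal_solid` and the pool. The 1-kcal floor matches
the pool gate and avoids chasing the asymptotic tail of the retention
curve; the discarded mass is logged per event.

**Blood volume.** Sex-specific cubic-height/linear-weight regressions
(female and male coefficients differ; both yield liters, scaled to dL).
Mixed-sex cohorts are handled by a sex-fraction-weighted mean blood
volume (`cohort_blood_volume`, or `Scenario.v_blood`).

**PEth initialization.** A non-zero basal PEth level initializes the
bound pool at the binding/release flux balance,
`PEth_Bound = basal·(1 + kPEth_bind/kPEth_release)`, so a drink-free
simulation holds the basal level steady. The published account states
that both states are computed from the basal level and the parameters
without printing the closed form; flux balance is the unique choice
that makes the basal state stationary.

**PEth unit.** ng/mL internally (the unit of the long-term calibration
data); conversions to µmol/L use the PEth 16:0/18:1 molar mass
703 g/mol (`PETH_MOLAR_MASS`).

## Parameters

`ModelParameters()` returns the published best-fit estimate of the 17
rate/affinity constants; `PARAMETER_BOUNDS` carries the estimation box
(1e-5 to 1e5 generically; the two hepatic Michaelis constants are
restricted to literature ranges: km_ADH ∈ [0.922, 9.22] mg/dL,
km_CYP2E1 ∈ [36.88, 46.1] mg/dL). Structurally informative parameters:
`Vmax, km, kKcal` (liquid emptying), `kKcal_clearance` (liquid-calorie
decay), `kPool_In/kPool_Out` (meal encapsulation), `k3/k4` (absorption
vs first-pass loss; at the published values ~91% of intestinal ethanol
never reaches blood), `Vmax_ADH/km_ADH/Vmax_CYP2E1/km_CYP2E1` (hepatic
clearance), `k6` (acetate clearance), and the PEth quartet
`kPEth, kPEth_out, kPEth_bind, kPEth_release`. The PEth subsystem is a
fast-binding/slow-release two-pool exchange: free PEth equilibrates
with the bound pool on milliseconds, while the effective elimination
rate of the bound pool is the composite
`kPEth_out·kPEth_release/kPEth_bind ≈ 5.2e-5 min⁻¹` (half-life ≈ 9
days), which is what makes PEth a months-scale marker.

## Numerics

- LSODA (stiff) by default, rtol 1e-8 / atol 1e-10; integration is
  restarted at every drink start/stop and meal time so no discontinuity
  is stepped over blindly. The output grid is evaluated from the dense
  solution and never alters the solver path, so coarse-grid results are
  exact restrictions of fine-grid results.
- Peak BAC is refined by re-sampling the dense solution around the
  best solver step rather than read off the output grid.
- Trajectory non-negativity is monitored; an excursion below −10·atol
  is logged as a warning event rather than silently clipped. A
  non-positive stomach volume raises immediately — it signals solver
  failure, never a patched state.
- Day-chaining (`simulate_days`) carries the full state across
  midnight; intermediate days skip dense output for speed. The
  reproducibility-relevant problem sizes: the 90-day × 5-BMI × 2-sex
  sweep used by the acceptance script chains 900 day-long stiff
  integrations (~2 min total on one core).
- The fit is a seeded multi-start search: log-uniform starts in the
  box, L-BFGS-B refinement over log-parameters, geometric recombination
  of elite survivors, then re-refinement. Any two runs with the same
  seed are identical; the trace of every start is returned.
- Profiling optimizes the penalized objective with bounded Powell
  searches (the penalty kink rules out gradient methods), multi-started
  with multiplicative jitter, in log-parameter space for the model (the
  constants span ten decades). Achieving points are accepted only
  within a 1e-6 relative feasibility tolerance on the threshold. The
  printed penalty is scaled by the property's start value, so profiling
  a property whose start value is exactly 0 leaves the infeasible
  region unpenalized — start from the best fit, not from a zero
  crossing.

## Synthetic data

The generator mirrors the structure of the calibration datasets: per
study a scenario, observable kinds, sampling times, and n Gaussian
replicates per point, summarized as mean and SEM = s/√n. Defaults fixed
up front: σ = 10% of the observable's trajectory peak, n = 10
replicates. Because the SEM is *estimated*, the cost at the generating
parameters is a sum of squared t-statistics, mean (n−1)/(n−3) per
point — slightly above the idealized χ² value of 1; the Monte-Carlo
test asserts exactly this.

What passing on synthetic data does not show: the generator draws
independent Gaussian noise around the model's own trajectories, so it
cannot expose structural misfit, correlated measurement error,
between-subject variability, or digitization bias — conclusions about
real cohorts still require the external datasets.

## Scenario conventions for the long-term predictions

The published BMI sweeps vary weight only; heights are not printed.
Fixed reference heights of 1.66 m (female) and 1.80 m (male) with
weight = BMI·height² are used, and "one standard glass of wine" (15 cL,
13.5 v/v%) is consumed over 20 min — matching the printed durations of
the single-drink calibration scenarios — with the daily meal at the
same time as the drink. All three choices are exposed as plain
arguments.

## Known limitations

- At the published point estimate, the male two-glass daily schedule
  accumulates day-90 free PEth to ≈0.25 µmol/L (the acceptance script's
  t6), above the 0.007–0.17 µmol/L range reported for the corresponding
  clinical cohort; the female schedule stays inside it. The prediction
  is insensitive to the unprinted scenario details (drink duration,
  meal timing); a modestly faster PEth clearance inside the published
  parameter uncertainty would lower it into range, so treat absolute
  long-term PEth levels as carrying at least that much model
  uncertainty.
- Rejected alternative meal-effect mechanisms (delayed liquid
  emptying, gastric ADH, food-stimulated hepatic blood flow) are not
  implemented — only the accepted encapsulation mechanism is.
- No acetaldehyde intermediate, carbonation effects,
  macronutrient-specific emptying, or enzyme-expression covariates; a
  single parameter set is shared across subjects, so same-dose differences
  between cohorts beyond anthropometrics are outside the model.
- The χ² validation threshold uses the standard quantile; dof equals
  the number of data points with no parameter-count correction.
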