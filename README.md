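# drinktwin

A physiologically-based **digital twin of alcohol consumption**: an ODE
model that simulates, for a specific person (sex, height, weight), how
timed drinks and meals turn into gastric emptying, blood alcohol
(BAC/BrAC), plasma acetate, and — over weeks to months — the clinical
consumption biomarker **phosphatidylethanol (PEth)**. The package also
contains the calibration machinery that makes such a model trustworthy:
an SEM-weighted least-squares cost over multi-study datasets, a χ²
rejection test, seeded multi-start global parameter estimation, and
profile-style min/max uncertainty for parameters and predictions.

It is intended for researchers in pharmacokinetic/systems-biology
modeling and for anyone building tools that relate self-reported
drinking to measured PEth levels.

## The model

Twelve states in one coupled system (time in min, volumes in dL,
ethanol in mg/dL, PEth in ng/mL):

- **Gastric emptying.** Liquid leaves the stomach through a
  Michaelis–Menten valve inhibited exponentially by the liquid caloric
  load, `r2 = Vmax · Vol_change/(Vol_change + km) · exp(−Kcal_Liquid/kKcal)`;
  solid meals empty along a Tougas power-exponential retention curve
  `exp(−(0.010·t)^1.86)`.
- **Meal effect on ethanol.** Stomach ethanol is reversibly
  encapsulated into solid food (the "food pool") down a concentration
  gradient; digestion shrinks the pool volume and releases ethanol
  back. When digestion completes, the residual pool is discarded — a
  meal-dependent first-pass loss that blunts and flattens the BAC
  curve.
- **Absorption and metabolism.** Emptied ethanol enters the intestines,
  is absorbed into blood (`k3`) or eliminated first-pass (`k4`), and is
  cleared hepatically by two saturable pathways (ADH and CYP2E1
  Michaelis–Menten terms), producing plasma acetate. Blood volume comes
  from sex-specific Nadler-type regressions of height and weight — this
  is where the twin is personalized.
- **PEth.** Formed from blood ethanol (`kPEth·BAC`), cleared from
  plasma, and exchanged with a large, slowly releasing lipid-bound pool
  — the bound pool integrates weeks of drinking while free PEth is what
  an assay measures.

Calibration: `V(θ) = Σ ((y − ŷ)/SEM)²` summed over studies, observables
and time points; the model is rejected at level α when `V(θ)` exceeds
the `1−α` χ² quantile with one degree of freedom per data point.
Uncertainty: any scalar property `p̂` (a parameter, or `ŷ(t)`) is
minimized/maximized subject to `V(θ) < T` via an L1 penalty relaxation.

## Worked example

One glass of wine (15 cL, 13.5 v/v%) with a 920 kcal dinner, every day
for 90 days, for a 62 kg / 1.66 m woman:

```python
import numpy as np
from drinktwin import *

person = Anthropometrics(sex=0, height=1.66, weight=62.0)
drinks = [DrinkEvent(start=0, duration=20, volume=0.15, ethanol_vv=13.5)]
meals  = [MealEvent(time=0.0, kcal=920.0)]
sched  = compile_schedule(drinks, meals, horizon=1440.0)

traj = simulate(sched, person, grid=np.linspace(0, 1440, 1441))
days = simulate_days(drinks, meals, person, n_days=90)
```

This prints (via the obvious `print` statements):

```
blood volume        : 38.6 dL
ethanol dose        : 16.0 g
peak blood ethanol  : 10.3 mg/dL
peak breath alcohol : 0.0124 g/210L
event t=    0.0 min  meal         value=920.0
event t=  223.1 min  pool_reset   value=7801.1
day-90 PEth         : 47.8 ng/mL = 0.068 umol/L
```

Reading: the dinner keeps the single-glass BAC peak near 10 mg/dL
(≈0.01%, far below intoxication); about half of the 16 g dose is lost
with the discarded food pool at `pool_reset`; and daily repetition
accumulates free PEth to ≈48 ng/mL (0.068 µmol/L) by day 90 — inside
the range reported for compliant one-glass-per-day drinkers in the
three-month clinical study the model is validated against.

A command-line interface mirrors this: `twin scenarios` lists packaged
reference scenarios, `twin simulate --scenario my.yaml --out traj.csv`
writes a trajectory, `twin synth` draws synthetic observation tables,
and `twin profile` computes parameter uncertainty intervals.

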