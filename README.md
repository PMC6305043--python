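# cpropt

Mechanistic optimization of cardiopulmonary resuscitation (CPR) parameters
against a closed-form blood-gas-delivery model.

During CPR a rescuer controls a handful of quantities — the
compression-to-ventilation ratio *x*, the time per compression *t* (so 1/*t*
is the compression speed), the ventilation pause *T*, the tidal volume
*v<sub>t</sub>* and the inspired gas fractions
*f<sub>I</sub>O₂*, *f<sub>I</sub>CO₂* — while each patient contributes a
maximum achievable blood flow *Q*<sub>max</sub>. `cpropt` models the total
blood-gas delivery (systemic O₂ delivery plus CO₂ delivery to the lungs)
as a function of these parameters and finds, per patient group, the
parameter settings that maximize it. It is aimed at resuscitation-modelling
researchers who want a reproducible, seedable implementation of this
optimization to probe, extend, or compare against other physiological
models — not at clinical use.

## Model

Delivery of a blood gas is mean flow times concentration change,
D = Q̄·ΔC, with

- Q̄ = Q<sub>max</sub>·x / (T/t + x) — flow is generated only by
  compressions, vanishing at x = 0 and saturating at Q<sub>max</sub>;
- alveolar fractions from a steady-state alveolar mass balance between
  effective ventilation (v<sub>t</sub> − v<sub>d</sub>)·R and perfusive
  uptake (v<sub>d</sub> = dead space, R = ventilation rate,
  s<sub>O₂</sub>/s<sub>CO₂</sub> = linearized dissociation-curve slopes):

  f<sub>A</sub>O₂ = (v<sub>t</sub>−v<sub>d</sub>)R·f<sub>I</sub>O₂ / [(v<sub>t</sub>−v<sub>d</sub>)R + Q̄·s<sub>O₂</sub>],  
  f<sub>A</sub>CO₂ = (v<sub>t</sub>−v<sub>d</sub>)R·f<sub>I</sub>CO₂ / [(v<sub>t</sub>−v<sub>d</sub>)R − Q̄·s<sub>CO₂</sub>];

- ΔC = s·f<sub>A</sub> (linear dissociation range), and the objective
  D<sub>Total</sub> = D<sub>O₂</sub> + D<sub>CO₂</sub> (optionally
  differentially weighted).

The published closed form for the two deliveries contains internal
inconsistencies (its CO₂ numerator carries the O₂ symbols and it implies
R = 1/t); the package ships three explicit variants — `as_printed`
(default, faithful), `corrected_co2`, and `explicit_R` (full composition
with R = 1/(x·t + T)) — and every consumer is parameterized over them.
See `docs/methods.md`.

Two optimization protocols maximize D<sub>Total</sub> with Metropolis
simulated annealing over the clinical parameter box:

- **global** — one annealing run over all six rescuer parameters;
- **sequential** — per CPR cycle, optimize *x* alone, perform the cycle,
  then optimize the remaining parameters at fixed *x*, warm-starting each
  cycle at the previous best.

An exhaustive grid-search oracle (9 points per dimension ≈ 5.3×10⁵
evaluations) provides ground truth for validating both.

## Worked example

```python
from cpropt import PatientParams, RescuerParams, blood_gas_delivery

rescuer = RescuerParams(T=0.133, t=0.01, x=30.0, v_t=800.0,
                        f_I_O2=0.16, f_I_CO2=0.0004)
snap = blood_gas_delivery(PatientParams(Q_max=1000.0), rescuer)
print(f"Q_bar   = {snap.Q_bar:.2f} mL/min")
print(f"D_O2    = {snap.D_O2:.2f} mL/min")
print(f"D_CO2   = {snap.D_CO2:.2f} mL/min")
print(f"D_total = {snap.D_total:.2f} mL/min")
```

prints

```
Q_bar   = 692.84 mL/min
D_O2    = 163.66 mL/min
D_CO2   = 167.71 mL/min
D_total = 331.38 mL/min
```

i.e. at the conventional 30:1 ratio a patient capable of 1000 mL/min
achieves a mean flow of ≈ 693 mL/min and ≈ 331 mL gas/min of combined
delivery. Optimizing instead of using the conventional settings:

```sh
cpropt optimize --q-max 900 --scheme sequential --seed 1 --out results/
cpropt sweep --seed 1 --out results/        # full patient-group sweep
cpropt oracle --q-max 900 --points 9        # exhaustive grid reference
```

The sweep writes `summary.csv` (one row per scheme × Q_max: final
parameters and deliveries), `trajectory.csv` (per-cycle series of x, T,
1/t, v_t and deliveries), `trend_report.csv` (qualitative per-cycle trend
flags, informational only), and the fully-resolved `config_resolved.yaml`.
Every knob — bounds, model variant, objective weights, annealing schedule,
sweep grid — can be set in a YAML/JSON file passed via `--config`; unknown
keys are rejected by name.

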