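# Methods

## The delivery model

The model treats one "patient group" as a fixed maximum blood flow
Q_max (mL/min), shared between the systemic and pulmonary circulations
(balanced flow is assumed, so a single Q̄ serves both deliveries). The
rescuer-controlled parameters and their admissible ranges are:

| parameter | meaning | unit | default bounds |
|---|---|---|---|
| T | ventilation pause per breath | min | [0.132, 0.134] |
| t | time per compression (1/t = compression speed) | min | [0.008, 0.012] |
| x | compressions per ventilation | — | [5, 100] |
| v_t | tidal volume | mL | [600, 1000] |
| f_I_O2 | inspired O₂ fraction | — | [0.13, 0.19] |
| f_I_CO2 | inspired CO₂ fraction | — | [0.0002, 0.0006] |

Constants: dead space v_d = 150 mL, dissociation-curve slopes
s_O2 = 1.5 and s_CO2 = 0.8 mL gas/mL blood. All times are minutes,
volumes mL, flows mL/min; no unit conversion happens anywhere in the
core. The bounds for x are our own choice — the published table gives
none although x is optimized — set to bracket conventional 15:2/30:2
practice and the above-30 ratios the model favors. The patient sweep
defaults to Q_max ∈ [700, 1100] mL/min (the range the headline results
use); the alternative tabulated range [400, 1000] is available as
`ParameterBounds.table_preset()`.

Mean flow is Q̄ = Q_max·x/(T/t + x). Alveolar fractions come from the
steady-state alveolar mass balance, concentration changes are linear in
the alveolar fractions (ΔC = s·f_A), and each delivery is D = Q̄·ΔC. The
CO₂ balance has a pole: when perfusive uptake Q̄·s_CO2 reaches the
effective alveolar ventilation (v_t−v_d)·R there is no steady state.
Crossing that denominator raises a typed `SingularityError` rather than
returning an infinity — the optimizers treat such points as infeasible,
otherwise the annealer would chase a nonphysical pole where "delivery"
diverges.

### Formula variants

The published closed form for the deliveries is internally inconsistent
with the mass-balance derivation it summarizes: its CO₂ numerator carries
s_O2 and f_I_O2 (the oxygen symbols), and recovering it from the alveolar
balance forces a ventilation rate of R = 1/t (one breath per
*compression*), which contradicts the cycle structure of one breath per
x compressions. Neither reading can be established as intended, so the
package ships all three as first-class variants:

- `as_printed` (default): the closed form exactly as published. Chosen
  as default for faithfulness — all headline numbers use it.
- `corrected_co2`: the same structure with the CO₂ numerator symbols
  swapped to s_CO2·f_I_CO2. Note this makes D_CO2 numerically tiny
  (~0.2 vs ~168 mL/min at the reference point), so the total objective
  becomes essentially oxygen-driven.
- `explicit_R`: the full composition D = Q̄·s·f_A with
  R = 1/(x·t + T) — one ventilation per full
  compressions-plus-ventilation cycle, the only dimensionally coherent
  reading of "average ventilation rate" we could construct from the cycle
  structure.

For the closed-form variants the snapshot's alveolar fractions are backed
out as f_A = D/(Q̄·s) (with f_A = f_I at zero flow), so every reported
intermediate is consistent with the reported deliveries.

A consequence worth knowing: under `as_printed`, D_total is strictly
increasing in x across the entire box, so the static optimum pins x at
its upper bound. Decreasing-ratio trajectories therefore cannot emerge
from this objective alone (see "Trend report" below).

### Dead-space limit

Both delivery numerators scale with (v_t − v_d), but so does the CO₂
denominator: for any fixed x > 0 the point exits the feasible region
before v_t reaches v_d. The "deliveries vanish with effective tidal
volume" property therefore holds unconditionally for D_O2 and along
feasible paths (x scaled down with v_t − v_d) for D_CO2; tests exercise
it in exactly that form.

## Simulated annealing

The annealer minimizes energy = −(weighted delivery) over the bounded
box (maximization is handled by that single negation at the scheme
layer, since the free-energy formalism is written for minimization).
Realization choices, none of which are prescribed by the formalism:

- **Metropolis acceptance**: downhill always, uphill with
  exp(−ΔE/temperature).
- **Geometric cooling**, t_{k+1} = 0.9·t_k, 100 proposals per
  temperature, stopping at 10⁻⁴ (objective units, i.e. mL/min). The
  budget (~10–15k evaluations per run, well under a second) was sized so
  the annealer reliably reaches the exhaustive grid optimum within a few
  tenths of a percent on the delivery objectives; the documented
  contract is dominance within 0.5%.
- **Initial temperature** auto-calibrated from 100 seeded probe
  proposals at the start point so the median uphill move is accepted
  with probability ≈ 0.8 — this removes an otherwise arbitrary magic
  number and adapts to the objective's scale.
- **Proposals**: uniform steps of half-width `neighbor_scale`
  (default 0.15) times each bound width, *reflected* (not clipped) at
  the bounds so probability mass does not pile up on corners — relevant
  because the delivery objective attains corner optima in several
  coordinates. The width decays with √(T/T₀) (floored at 2%) so the cold
  phase refines locally. Half of all proposals perturb a single random
  coordinate instead of all six; without this, weakly-sensitive
  coordinates (v_t moves the objective by only ~0.3% across its full
  range) freeze mid-range because their small gains are drowned by joint
  noise in the sensitive ones.
- Proposals that raise a singularity or domain error get infinite
  energy: never accepted, never incumbent.
- The Helmholtz free-energy diagnostic (Boltzmann occupation over a
  finite state set) is exposed for inspecting low-temperature ordering;
  it plays no role in the search loop.

Runs are bitwise deterministic given (seed, config, start, objective);
one `numpy` Generator drives calibration, proposals, and acceptance.

## Optimization schemes

**Global**: one annealing run over all six rescuer parameters; the
trajectory is the per-temperature sequence of incumbent bests.

**Sequential**: per CPR cycle — (1) start at nominal values (bound
midpoints with x = 30, the conventional ratio); (2) anneal x alone under
the per-cycle proposal budget (default 600); (3) record the cycle the
rescuer would perform; (4) anneal the other five parameters at fixed x;
(5) repeat, warm-starting at the previous best, until converged. "Reaches
the maximum" is operationalized as relative improvement below
`convergence_tol` (default 10⁻⁴) for `patience` (default 2) consecutive
cycles, capped at `max_cycles` (default 15); no stopping rule is
prescribed by the protocol itself, so this is our choice. Warm-starting
guarantees the best-so-far delivery is non-decreasing across cycles —
an invariant the tests assert for every run.

An optional per-cycle **rate limit** restricts each parameter's movement
per cycle to a fraction of its bound width (implemented by intersecting
the annealing box with a movement box around the previous best). It is
**off by default**: the minimal faithful reading of the protocol has no
such limit, but gradual multi-cycle trajectories only arise with it on,
so the shape of trajectory plots depends on this knob.

Both schemes optimize the same static objective, so at convergence they
must agree; the package asserts agreement within 1% across the sweep and
reports (but does not assert) any ordering between them. For a static
objective a converged global optimum cannot be beaten by resequencing —
any "dynamically adapting" advantage of the sequential protocol would
require a time-varying patient state (e.g. blood-gas store depletion),
which this model does not include.

## Grid oracle

`grid_search` evaluates the weighted delivery on the full Cartesian grid
(endpoints inclusive, uniform spacing; corners must be on the grid
because corner optima are provably relevant), skips infeasible points,
and returns the exact grid maximum. The default 9 points/dimension over
six parameters is ≈ 5.3×10⁵ evaluations, vectorized with numpy (< 1 s);
a configurable cap (10⁷) guards against accidental combinatorial
explosions. A dedicated test checks the vectorized evaluation against
the scalar snapshot path point-by-point on a small grid.

## Patient-group sweep and synthetic cohorts

The sweep runs both schemes at Q_max ∈ {700, 800, 900, 1000, 1100}
mL/min (step 200 available via `SweepConfig.from_range`), asserts that
optimized delivery increases strictly with Q_max within each scheme (it
must: both deliveries are strictly increasing in Q_max at fixed
parameters, hence so is the optimum), and tabulates final parameters,
deliveries and per-cycle series. `generate_patient_cohort` samples
synthetic patients with Q_max uniform over a range (default 700–1100);
uniform sampling is a neutral choice — nothing in the model constrains
the population distribution of Q_max. These synthetic cohorts vary a
*single* scalar per patient; real patients differ in dead space,
dissociation-curve shape, and time-varying physiology, none of which the
generator emulates — so passing sweeps demonstrate properties of the
model and optimizers, not clinical claims.

### Trend report

Per-cycle qualitative trends of clinical interest — compression ratio
non-increasing after the first cycle, compression speed non-decreasing,
ventilation time constant within its (very narrow) bounds — are computed
by `trend_report` and written to `trend_report.csv` as booleans. They
are deliberately **non-blocking**: under the faithful static objective
the optimized x goes to its upper bound in cycle 1 and stays there, so
the decreasing-ratio dynamic cannot be guaranteed (it emerges only with
the rate limit on, as a transient of the start point). Recording
pass/fail keeps the observation honest without asserting something the
model does not imply. Ventilation-time constancy is trivially forced by
its bounds ([0.132, 0.134] min) and is asserted in tests.

## Numerical choices and degenerate inputs

- Zero-width bounds pin a parameter exactly (proposals leave it at the
  bound); a fully collapsed box returns the single point's direct
  evaluation.
- Zero flow (x = 0): alveolar fractions equal the inspired fractions and
  all deliveries are exactly 0.
- Ties in the grid search break toward the first index in C order —
  fixed by the deterministic grid construction, so repeat runs are
  identical.
- `convergence_check` guards the relative-improvement denominator with
  1e-300 to tolerate an (unreachable in practice) all-zero objective.
- CSVs are written at full double precision; a round-trip test re-evaluates
  the model at reported rows and requires agreement to 1e-9 relative.

## Problem sizes

Defaults were sized for interactive desk use: a global annealing run is
~10–15k model evaluations (< 0.5 s), the full two-scheme, five-group
sweep a few seconds, and the 9-per-dimension oracle under a second per
patient group. The acceptance script's complete recomputation runs in a
few seconds on one core.

## Known limitations

- Static physiology: Q_max is constant within a run; oxygen-store
  depletion and CO₂ accumulation over CPR time are not modelled, which
  is precisely why the sequential scheme cannot outperform the global
  one here.
- The linear dissociation-curve assumption (ΔC = s·f_A) is only valid
  for small concentration excursions.
- The `as_printed` variant inherits the publication's internal
  inconsistencies by design; conclusions sensitive to the CO₂ term
  should be checked against `corrected_co2` and `explicit_R`.
- Optimized parameters sit at box corners for several coordinates;
  results are therefore sensitive to the chosen clinical bounds, most of
  which are narrow, expert-chosen ranges.
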