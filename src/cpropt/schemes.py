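"""Global and sequential optimization of rescuer parameters at fixed Q_max.

Two protocols maximize the (optionally weighted) total blood-gas delivery
over the rescuer-controlled parameters for one patient:

* **global** — a single simulated-annealing run over all six rescuer
  parameters simultaneously.
* **sequential** — a per-CPR-cycle alternation: each cycle first optimizes
  the compression-to-ventilation ratio ``x`` alone (the rescuer then
  performs that cycle), then optimizes the remaining five parameters with
  ``x`` fixed; the cycle's best parameters warm-start the next cycle, so
  the best delivery is non-decreasing across cycles.  The loop stops when
  the relative improvement stays below a tolerance for a configured number
  of cycles, or at ``max_cycles``.

Both schemes minimize the negated weighted delivery through the annealer;
maximization is handled by that single negation here.  An optional
per-cycle rate limit caps how far any parameter may move in one cycle
(as a fraction of its bound width), for producing gradual trajectories;
it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional

from .annealer import AnnealingConfig, anneal
from .model_core import (
    DeliverySnapshot,
    DomainError,
    InfeasibilityError,
    ModelConstants,
    ModelVariant,
    ParameterBounds,
    PatientParams,
    RESCUER_PARAM_NAMES,
    RescuerParams,
    SingularityError,
    blood_gas_delivery,
    weighted_total_delivery,
)

__all__ = [
    "SchemeConfig",
    "CPRSequenceRecord",
    "OptimizationOutcome",
    "global_optimize",
    "sequential_optimize",
    "convergence_check",
]

Phase = Literal["ratio_step", "others_step", "global_step"]

# Parameters re-optimized in the second phase of each CPR cycle.
OTHER_PARAM_NAMES = tuple(n for n in RESCUER_PARAM_NAMES if n != "x")


@dataclass(frozen=True)
class SchemeConfig:
    """Configuration of one optimization protocol run.

    ``per_cycle_budget`` caps the annealer proposals spent in each phase of
    a sequential cycle.  ``rate_limit``, when set, restricts every
    parameter's per-cycle movement to that fraction of its bound width
    (None disables the limit).  ``nominal_start`` defaults to the bound
    midpoints with the conventional ratio x = 30.
    """

    scheme: Literal["global", "sequential"] = "global"
    variant: ModelVariant | str = ModelVariant.AS_PRINTED
    weights: tuple[float, float] = (1.0, 1.0)
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)
    constants: ModelConstants = field(default_factory=ModelConstants)
    per_cycle_budget: int = 600
    rate_limit: Optional[float] = None
    convergence_tol: float = 1e-4
    patience: int = 2
    max_cycles: int = 15
    nominal_start: Optional[RescuerParams] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("global", "sequential"):
            raise DomainError(f"unknown scheme {self.scheme!r}")
        if self.convergence_tol <= 0:
            raise DomainError("convergence_tol must be > 0")
        if self.max_cycles < 1:
            raise DomainError("max_cycles must be >= 1")
        if self.patience < 1:
            raise DomainError("patience must be >= 1")
        if self.per_cycle_budget < 1:
            raise DomainError("per_cycle_budget must be >= 1")
        if self.rate_limit is not None and not 0.0 < self.rate_limit <= 1.0:
            raise DomainError("rate_limit must lie in (0, 1] or be None")
        object.__setattr__(self, "variant", ModelVariant.coerce(self.variant))
        w_o2, w_co2 = self.weights
        if w_o2 < 0 or w_co2 < 0:
            raise DomainError("weights must be nonnegative")


@dataclass(frozen=True)
class CPRSequenceRecord:
    """Best parameters and their delivery after one optimization phase."""

    cycle_index: int
    phase: Phase
    rescuer: RescuerParams
    snapshot: DeliverySnapshot
    objective: float  # weighted total delivery at these parameters


@dataclass(frozen=True)
class OptimizationOutcome:
    """Trajectory and final optimum of one scheme × patient run."""

    scheme: str
    patient: PatientParams
    trajectory: tuple[CPRSequenceRecord, ...]
    converged: bool
    cycles_run: int

    @property
    def final(self) -> CPRSequenceRecord:
        return self.trajectory[-1]


def _resolve_start(config: SchemeConfig, bounds: ParameterBounds) -> RescuerParams:
    if config.nominal_start is not None:
        return config.nominal_start
    return bounds.midpoint_rescuer(x=30.0 if bounds.x[0] <= 30.0 <= bounds.x[1] else None)


def _objective_factory(patient, config):
    """Energy = negated weighted delivery; singularities propagate to the
    annealer, which treats them as infeasible."""
    w_o2, w_co2 = config.weights

    def energy(params: Mapping[str, float]) -> float:
        rescuer = RescuerParams(**{n: params[n] for n in RESCUER_PARAM_NAMES})
        snap = blood_gas_delivery(patient, rescuer, config.constants, config.variant)
        return -weighted_total_delivery(snap, w_o2, w_co2)

    return energy


def _record(patient, config, params: Mapping[str, float], cycle: int, phase: Phase):
    rescuer = RescuerParams(**{n: params[n] for n in RESCUER_PARAM_NAMES})
    snap = blood_gas_delivery(patient, rescuer, config.constants, config.variant)
    obj = weighted_total_delivery(snap, *config.weights)
    return CPRSequenceRecord(
        cycle_index=cycle, phase=phase, rescuer=rescuer, snapshot=snap, objective=obj
    )


def global_optimize(
    patient: PatientParams,
    bounds: ParameterBounds = ParameterBounds(),
    config: SchemeConfig = SchemeConfig(),
) -> OptimizationOutcome:
    """Single annealing run over all six rescuer parameters at once.

    The outcome's trajectory is the per-temperature sequence of best states,
    so it traces how the incumbent optimum improves as the system cools.
    Deterministic under ``config.annealing.seed``.
    """
    start = _resolve_start(config, bounds)
    energy = _objective_factory(patient, config)
    try:
        result = anneal(energy, bounds.rescuer_box(), config.annealing, start.as_dict())
    except Exception as exc:
        if isinstance(exc, (SingularityError, DomainError)):
            raise InfeasibilityError(
                f"global optimization start point infeasible at Q_max={patient.Q_max}: {exc}"
            ) from exc
        raise
    trajectory = tuple(
        _record(patient, config, s.parameters, i, "global_step")
        for i, s in enumerate(result.stage_bests)
    )
    if not trajectory:
        trajectory = (_record(patient, config, result.best_state.parameters, 0, "global_step"),)
    return OptimizationOutcome(
        scheme="global",
        patient=patient,
        trajectory=trajectory,
        converged=True,
        cycles_run=len(trajectory),
    )


def _rate_limited_box(
    box: Mapping[str, tuple[float, float]],
    center: Mapping[str, float],
    rate_limit: Optional[float],
    free: tuple[str, ...],
) -> dict[str, tuple[float, float]]:
    """Intersect the free parameters' bounds with a per-cycle movement box."""
    out: dict[str, tuple[float, float]] = {}
    for name in free:
        lo, hi = box[name]
        if rate_limit is not None:
            half = rate_limit * (hi - lo)
            lo2, hi2 = center[name] - half, center[name] + half
            lo, hi = max(lo, lo2), min(hi, hi2)
        out[name] = (lo, hi)
    return out


def _phase_config(config: SchemeConfig, seed: int) -> AnnealingConfig:
    return replace(
        config.annealing, seed=seed, max_proposals=config.per_cycle_budget
    )


def convergence_check(
    objectives: list[float] | tuple[float, ...], tol: float, patience: int
) -> bool:
    """True iff the best objective improved by less than ``tol`` (relative)
    over each of the last ``patience`` cycles.

    ``objectives`` is the per-cycle best weighted delivery, one entry per
    completed CPR cycle.
    """
    if len(objectives) < patience + 1:
        return False
    recent = objectives[-(patience + 1):]
    for prev, cur in zip(recent, recent[1:]):
        denom = max(abs(prev), 1e-300)
        if (cur - prev) / denom >= tol:
            return False
    return True


def sequential_optimize(
    patient: PatientParams,
    bounds: ParameterBounds = ParameterBounds(),
    config: SchemeConfig = SchemeConfig(scheme="sequential"),
) -> OptimizationOutcome:
    """Per-CPR-cycle alternating optimization.

    Each cycle anneals the compression-to-ventilation ratio ``x`` alone
    (emitting a ``ratio_step`` record — the point at which the rescuer
    performs the cycle), then anneals the remaining rescuer parameters with
    ``x`` fixed (an ``others_step`` record).  Cycles warm-start at the
    previous best, so the best delivery never decreases; iteration stops on
    convergence or at ``max_cycles``.
    """
    start = _resolve_start(config, bounds)
    energy = _objective_factory(patient, config)
    box = bounds.rescuer_box()
    current = dict(start.as_dict())

    try:
        energy(current)
    except (SingularityError, DomainError) as exc:
        raise InfeasibilityError(
            f"sequential optimization start point infeasible at Q_max={patient.Q_max}: {exc}"
        ) from exc

    records: list[CPRSequenceRecord] = []
    per_cycle_best: list[float] = []
    converged = False
    base_seed = config.annealing.seed
    cycles = 0

    for cycle in range(config.max_cycles):
        cycles = cycle + 1
        # Phase 1: ratio only.
        ratio_box = _rate_limited_box(box, current, config.rate_limit, ("x",))
        res = anneal(energy, ratio_box, _phase_config(config, (base_seed + 2 * cycle) % (2**31 - 1)), current)
        current = dict(res.best_state.parameters)
        records.append(_record(patient, config, current, cycle, "ratio_step"))

        # Phase 2: remaining rescuer parameters, x fixed.
        others_box = _rate_limited_box(box, current, config.rate_limit, OTHER_PARAM_NAMES)
        res = anneal(energy, others_box, _phase_config(config, (base_seed + 2 * cycle + 1) % (2**31 - 1)), current)
        current = dict(res.best_state.parameters)
        records.append(_record(patient, config, current, cycle, "others_step"))

        per_cycle_best.append(records[-1].objective)
        if convergence_check(per_cycle_best, config.convergence_tol, config.patience):
            converged = True
            break

    return OptimizationOutcome(
        scheme="sequential",
        patient=patient,
        trajectory=tuple(records),
        converged=converged,
        cycles_run=cycles,
    )
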