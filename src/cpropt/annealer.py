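"""Bounded continuous simulated annealing with Metropolis acceptance.

The search minimizes an energy (here the negated blood-gas delivery) over a
box of named parameters.  Worse states are accepted with the Boltzmann
probability exp(−ΔE/temperature); the temperature follows a geometric
cooling schedule, providing the slow cooling that lets the walk escape
local minima before the low-temperature regime locks in the ordered,
low-energy states.  A Helmholtz free-energy diagnostic over a finite state
set is provided for inspecting that low-temperature behavior; it plays no
role in the search loop.

Proposals that raise a model singularity or domain error are treated as
infeasible (infinite energy): they are never accepted and never become the
incumbent best.  Out-of-box proposals are reflected back across the
violated bound rather than clipped, so probability mass does not pile up on
corners — relevant because the delivery objective attains corner optima in
several coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .model_core import DomainError, SingularityError

__all__ = [
    "InitializationError",
    "AnnealingConfig",
    "CandidateState",
    "AnnealingResult",
    "acceptance_probability",
    "free_energy",
    "propose_neighbor",
    "anneal",
]

Objective = Callable[[Mapping[str, float]], float]
Bounds = Mapping[str, tuple[float, float]]


class InitializationError(RuntimeError):
    """The annealing start point is infeasible under the objective."""


@dataclass(frozen=True)
class AnnealingConfig:
    """Knobs of one annealing run.

    ``initial_temperature`` is in objective units; when ``None`` it is
    calibrated from 100 seeded probe proposals at the start point so the
    median uphill move is accepted with probability ≈ 0.8.
    ``neighbor_scale`` is the proposal half-width as a fraction of each
    parameter's bound width.
    """

    initial_temperature: Optional[float] = None
    cooling_factor: float = 0.9
    steps_per_temperature: int = 100
    min_temperature: float = 1e-4
    neighbor_scale: float = 0.15
    seed: int = 0
    max_proposals: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise DomainError("cooling_factor must lie in (0, 1)")
        if self.steps_per_temperature < 1:
            raise DomainError("steps_per_temperature must be >= 1")
        if not 0.0 < self.neighbor_scale <= 1.0:
            raise DomainError("neighbor_scale must lie in (0, 1]")
        if self.min_temperature <= 0:
            raise DomainError("min_temperature must be > 0")
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise DomainError("initial_temperature must be > 0")


@dataclass(frozen=True)
class CandidateState:
    """A point in the search box with its energy (negated delivery).

    ``feasible`` is False when the objective raised a singularity/domain
    error at this point, in which case ``energy`` is +inf.
    """

    parameters: dict[str, float]
    energy: float
    feasible: bool = True


@dataclass
class AnnealingResult:
    best_state: CandidateState
    energy_trace: list[float] = field(default_factory=list)
    stage_bests: list[CandidateState] = field(default_factory=list)
    acceptance_count: int = 0
    proposal_count: int = 0
    final_temperature: float = float("nan")


def acceptance_probability(delta_energy: float, temperature: float) -> float:
    """Metropolis acceptance probability: 1 downhill, exp(−ΔE/T) uphill."""
    if temperature <= 0:
        raise DomainError("temperature must be strictly positive")
    if delta_energy <= 0:
        return 1.0
    return math.exp(-delta_energy / temperature)


def free_energy(energies: Sequence[float], temperature: float) -> float:
    """Helmholtz free energy Σ p·E + T·Σ p·log p over a finite state set.

    Occupation probabilities are Boltzmann weights p ∝ exp(−E/T),
    normalized over the given states.  Diagnostic only: at low temperature
    the result collapses onto the minimum energy, illustrating that ordered
    low-energy states dominate.
    """
    if temperature <= 0:
        raise DomainError("temperature must be strictly positive")
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise DomainError("free_energy requires at least one state")
    # log-sum-exp for a stable Boltzmann normalization
    z = -e / temperature
    z_max = z.max()
    log_p = z - (z_max + math.log(np.exp(z - z_max).sum()))
    p = np.exp(log_p)
    return float(np.dot(p, e) + temperature * np.dot(p, log_p))


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a value back into [lo, hi] by reflection at the bounds."""
    if hi == lo:
        return lo
    width = hi - lo
    period = 2.0 * width
    y = (value - lo) % period
    if y > width:
        y = period - y
    return lo + y


def propose_neighbor(
    state: CandidateState,
    bounds: Bounds,
    scale: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Perturb each bounded parameter by a uniform draw of width scale·(hi−lo).

    Results outside the box are reflected back in.  Zero-width bounds pin a
    parameter; scale = 0 returns the state unchanged.  Deterministic given
    the generator state.
    """
    out: dict[str, float] = dict(state.parameters)
    for name, (lo, hi) in bounds.items():
        width = hi - lo
        if width == 0.0 or scale == 0.0:
            out[name] = lo if width == 0.0 else out[name]
            continue
        step = rng.uniform(-scale * width, scale * width)
        out[name] = _reflect(out[name] + step, lo, hi)
    return out


def _evaluate(objective: Objective, params: Mapping[str, float]) -> tuple[float, bool]:
    try:
        e = float(objective(params))
    except (SingularityError, DomainError):
        return float("inf"), False
    if not math.isfinite(e):
        return float("inf"), False
    return e, True


def _calibrate_temperature(
    objective: Objective,
    start: CandidateState,
    bounds: Bounds,
    scale: float,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    probes: int = 100,
) -> float:
    """Initial temperature such that the median uphill probe is accepted
    with probability ``target_accept``; falls back to 1.0 in degenerate
    landscapes (no finite uphill move found)."""
    uphill: list[float] = []
    for _ in range(probes):
        cand = propose_neighbor(start, bounds, scale, rng)
        e, ok = _evaluate(objective, cand)
        if ok and e > start.energy:
            uphill.append(e - start.energy)
    if not uphill:
        return 1.0
    med = float(np.median(uphill))
    if med <= 0:
        return 1.0
    return med / (-math.log(target_accept))


def anneal(
    objective: Objective,
    bounds: Bounds,
    config: AnnealingConfig,
    start: Mapping[str, float],
) -> AnnealingResult:
    """Run Metropolis simulated annealing with geometric cooling.

    Parameters
    ----------
    objective : callable
        Maps a parameter mapping to an energy (minimized).  May raise
        :class:`~cpropt.model_core.SingularityError` /
        :class:`~cpropt.model_core.DomainError` to flag infeasible points.
    bounds : mapping
        ``name -> (lower, upper)`` box for every free parameter.  Parameters
        present in ``start`` but absent from ``bounds`` stay fixed.
    config : AnnealingConfig
    start : mapping
        Starting parameter values; must lie inside the box and evaluate
        to a finite energy.

    Returns
    -------
    AnnealingResult
        Best state found, per-step running-best energy trace, per-temperature
        best states, and acceptance counters.  Deterministic under
        ``config.seed``.
    """
    for name, (lo, hi) in bounds.items():
        v = start[name]
        if not lo <= v <= hi:
            raise DomainError(f"start[{name}]={v} outside bounds [{lo}, {hi}]")

    e0, ok = _evaluate(objective, start)
    if not ok:
        raise InitializationError(
            "objective is infeasible or non-finite at the start point"
        )
    current = CandidateState(dict(start), e0)
    best = current

    rng = np.random.default_rng(config.seed)
    temperature = config.initial_temperature
    if temperature is None:
        temperature = _calibrate_temperature(
            objective, current, bounds, config.neighbor_scale, rng
        )

    trace: list[float] = []
    stage_bests: list[CandidateState] = []
    accepted = 0
    proposals = 0
    budget = config.max_proposals
    t_start = temperature

    while temperature > config.min_temperature:
        # Proposal width tracks the annealing progress: wide early for
        # exploration, narrowing with sqrt(T/T0) (floored) so the cold
        # phase refines locally instead of re-jumping across the box.
        scale = config.neighbor_scale * max(
            math.sqrt(temperature / t_start), 0.02
        )
        names = list(bounds)
        for _ in range(config.steps_per_temperature):
            if budget is not None and proposals >= budget:
                break
            # Mixed move set: half the proposals perturb all coordinates
            # jointly, half a single random coordinate.  Single-coordinate
            # moves let weakly-sensitive parameters relax downhill without
            # their gain being drowned by joint noise in the others.
            if len(names) > 1 and rng.random() < 0.5:
                pick = names[rng.integers(len(names))]
                step_bounds = {pick: bounds[pick]}
            else:
                step_bounds = bounds
            cand_params = propose_neighbor(current, step_bounds, scale, rng)
            e, feasible = _evaluate(objective, cand_params)
            proposals += 1
            if feasible:
                p = acceptance_probability(e - current.energy, temperature)
                if p >= 1.0 or rng.random() < p:
                    current = CandidateState(cand_params, e)
                    accepted += 1
                    if e < best.energy:
                        best = current
            trace.append(best.energy)
        stage_bests.append(best)
        if budget is not None and proposals >= budget:
            break
        temperature *= config.cooling_factor

    return AnnealingResult(
        best_state=best,
        energy_trace=trace,
        stage_bests=stage_bests,
        acceptance_count=accepted,
        proposal_count=proposals,
        final_temperature=temperature,
    )
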