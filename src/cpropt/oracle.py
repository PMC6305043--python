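"""Exhaustive grid-search maximizer — ground truth for the stochastic schemes.

Evaluates the weighted total delivery on a full Cartesian grid over the
rescuer-parameter box (endpoints inclusive, uniform spacing — corners must
be on the grid because the delivery objective provably attains corner
optima in several coordinates) and returns the exact grid maximum.
Infeasible points (CO₂ singularity) are skipped.  The closed-form variants
are evaluated with the same vectorized expression the scalar model uses;
the explicit-R variant composes mean flow, ventilation rate, alveolar
fractions and concentration changes in array form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    DomainError,
    InfeasibilityError,
    ModelConstants,
    ModelVariant,
    ParameterBounds,
    PatientParams,
    RESCUER_PARAM_NAMES,
    RescuerParams,
    _closed_form_deliveries,
)

__all__ = ["GridSpec", "grid_search"]


@dataclass(frozen=True)
class GridSpec:
    """Points-per-dimension for the exhaustive sweep.

    ``points`` maps parameter names to counts; unnamed parameters default
    to ``default_points``.  The derived total evaluation count must stay
    under ``cap``.
    """

    points: dict[str, int] = field(default_factory=dict)
    default_points: int = 9
    cap: int = 10_000_000

    def __post_init__(self) -> None:
        for name, n in self.points.items():
            if name not in RESCUER_PARAM_NAMES:
                raise DomainError(f"unknown grid parameter {name!r}")
            if n < 1:
                raise DomainError(f"grid points for {name} must be >= 1")
        if self.default_points < 1:
            raise DomainError("default_points must be >= 1")

    def counts(self) -> dict[str, int]:
        return {
            name: self.points.get(name, self.default_points)
            for name in RESCUER_PARAM_NAMES
        }

    def total_evaluations(self) -> int:
        return math.prod(self.counts().values())


def _axes(bounds: ParameterBounds, grid: GridSpec) -> dict[str, np.ndarray]:
    axes = {}
    for name, n in grid.counts().items():
        lo, hi = getattr(bounds, name)
        if lo == hi or n == 1:
            axes[name] = np.array([0.5 * (lo + hi)]) if n == 1 else np.array([lo])
        else:
            axes[name] = np.linspace(lo, hi, n)
    return axes


def grid_search(
    patient: PatientParams,
    bounds: ParameterBounds = ParameterBounds(),
    grid: GridSpec = GridSpec(),
    variant: ModelVariant | str = ModelVariant.AS_PRINTED,
    weights: tuple[float, float] = (1.0, 1.0),
    constants: ModelConstants = ModelConstants(),
) -> tuple[RescuerParams, float]:
    """Exact maximum of the weighted delivery over the inclusive grid.

    Returns the argmax as :class:`RescuerParams` and the best objective
    value.  Deterministic and order-invariant (ties broken by the first
    index in C order, which is fixed by the grid construction).

    Raises
    ------
    DomainError
        If the grid exceeds its evaluation cap.
    InfeasibilityError
        If every grid point is infeasible.
    """
    variant = ModelVariant.coerce(variant)
    if grid.total_evaluations() > grid.cap:
        raise DomainError(
            f"grid of {grid.total_evaluations()} evaluations exceeds cap {grid.cap}"
        )
    axes = _axes(bounds, grid)
    mesh = np.meshgrid(*[axes[n] for n in RESCUER_PARAM_NAMES], indexing="ij")
    T, t, x, v_t, f_i_o2, f_i_co2 = [m.ravel() for m in mesh]
    w_o2, w_co2 = weights
    if w_o2 < 0 or w_co2 < 0:
        raise DomainError("weights must be nonnegative")

    v_d, s_o2, s_co2 = constants.v_d, constants.s_O2, constants.s_CO2
    q = patient.Q_max
    valid = (t > 0) & (v_t > v_d) & (x >= 0) & (T >= 0)

    if variant is ModelVariant.EXPLICIT_R:
        with np.errstate(divide="ignore", invalid="ignore"):
            q_bar = q * x / (T / t + x)
            r = 1.0 / (x * t + T)
            vent = (v_t - v_d) * r
            co2_den = vent - q_bar * s_co2
            f_a_o2 = vent * f_i_o2 / (vent + q_bar * s_o2)
            f_a_co2 = vent * f_i_co2 / co2_den
            d_o2 = q_bar * s_o2 * f_a_o2
            d_co2 = q_bar * s_co2 * f_a_co2
    else:
        corrected = variant is ModelVariant.CORRECTED_CO2
        d_o2, d_co2, co2_den = _closed_form_deliveries(
            q, T, t, x, v_t, f_i_o2, f_i_co2, v_d, s_o2, s_co2, corrected
        )
    valid &= co2_den > 0
    obj = w_o2 * d_o2 + w_co2 * d_co2
    obj = np.where(valid & np.isfinite(obj), obj, -np.inf)

    idx = int(np.argmax(obj))
    if not np.isfinite(obj[idx]):
        raise InfeasibilityError("every grid point is infeasible")
    best = RescuerParams(
        T=float(T[idx]), t=float(t[idx]), x=float(x[idx]), v_t=float(v_t[idx]),
        f_I_O2=float(f_i_o2[idx]), f_I_CO2=float(f_i_co2[idx]),
    )
    return best, float(obj[idx])
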