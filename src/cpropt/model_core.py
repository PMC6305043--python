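"""Closed-form alveolar gas-exchange and blood-gas-delivery model of CPR.

The model computes systemic oxygen delivery and carbon dioxide delivery to
the lungs during cardiopulmonary resuscitation as a function of six
rescuer-controlled parameters (ventilation time ``T``, compression time
``t``, compression-to-ventilation ratio ``x``, tidal volume ``v_t``, and
inspired fractions ``f_I_O2``/``f_I_CO2``), one patient parameter (maximum
blood flow ``Q_max``), and three physiological constants (dead space
``v_d`` and the linearized dissociation-curve slopes ``s_O2``/``s_CO2``).

Delivery of a blood gas is the product of mean blood flow and the change in
blood-gas concentration across the exchange site, D = Q̄·ΔC.  Mean blood
flow during CPR is Q̄ = Q_max·x/(T/t + x): flow is generated only by
compressions, so it vanishes at x = 0 and saturates at Q_max as x → ∞.
Alveolar fractions follow from a steady-state mass balance between
effective alveolar ventilation (v_t − v_d)·R and perfusive uptake, and
concentration changes are linear in the alveolar fractions (the model works
in the linear range of the dissociation curves).

Units: all times in minutes, volumes in mL, flows in mL/min, gas fractions
dimensionless.  No unit conversion happens anywhere in this module.

Because the published closed form for the CO₂ delivery reuses the oxygen
symbols in its numerator and implies a ventilation rate of one breath per
compression, three explicit model variants are provided (see
:class:`ModelVariant`); every downstream consumer is parameterized over
them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

__all__ = [
    "DomainError",
    "SingularityError",
    "InfeasibilityError",
    "ModelConstants",
    "RescuerParams",
    "PatientParams",
    "ParameterBounds",
    "ModelVariant",
    "DeliverySnapshot",
    "mean_blood_flow",
    "ventilation_rate",
    "alveolar_fractions",
    "delta_concentrations",
    "blood_gas_delivery",
    "weighted_total_delivery",
    "validate_domain",
    "RESCUER_PARAM_NAMES",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class DomainError(ValueError):
    """A parameter lies outside the model's physical domain."""


class SingularityError(ArithmeticError):
    """The CO₂ balance denominator is nonpositive.

    Signals perfusion exceeding effective alveolar ventilation; the model
    has no steady state there and optimizers must treat the point as
    infeasible rather than chase the pole.
    """


class InfeasibilityError(RuntimeError):
    """No feasible point was found in a search."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

RESCUER_PARAM_NAMES = ("T", "t", "x", "v_t", "f_I_O2", "f_I_CO2")


@dataclass(frozen=True)
class ModelConstants:
    """Physiological constants.

    Parameters
    ----------
    v_d : float
        Dead-space volume, mL.
    s_O2 : float
        Slope of the O₂ dissociation curve, mL gas per mL blood.
    s_CO2 : float
        Slope of the CO₂ dissociation curve, mL gas per mL blood.
    """

    v_d: float = 150.0
    s_O2: float = 1.5
    s_CO2: float = 0.8

    def __post_init__(self) -> None:
        for name in ("v_d", "s_O2", "s_CO2"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RescuerParams:
    """The six rescuer-controlled quantities the optimizers vary.

    Parameters
    ----------
    T : float
        Average artificial ventilation time (pause per breath), min.
    t : float
        Time for one full compression, min; 1/t is the compression speed.
    x : float
        Compression-to-ventilation ratio (compressions per breath).
    v_t : float
        Tidal volume, mL.
    f_I_O2, f_I_CO2 : float
        Inspired O₂ and CO₂ fractions, dimensionless.
    """

    T: float
    t: float
    x: float
    v_t: float
    f_I_O2: float
    f_I_CO2: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise DomainError("compression time t must be strictly positive")
        if self.T < 0:
            raise DomainError("ventilation time T must be nonnegative")
        if self.x < 0:
            raise DomainError("compression-to-ventilation ratio x must be nonnegative")
        if self.v_t <= 0:
            raise DomainError("tidal volume v_t must be strictly positive")
        if not 0.0 <= self.f_I_O2 <= 1.0:
            raise DomainError("f_I_O2 must lie in [0, 1]")
        if not 0.0 <= self.f_I_CO2 <= 1.0:
            raise DomainError("f_I_CO2 must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RESCUER_PARAM_NAMES}


@dataclass(frozen=True)
class PatientParams:
    """Patient-dependent parameter: maximum blood flow, mL/min.

    A single ``Q_max`` serves as both the maximum systemic and the maximum
    pulmonary flow — the model assumes balanced systemic and pulmonary
    circulation during CPR.
    """

    Q_max: float

    def __post_init__(self) -> None:
        if self.Q_max <= 0:
            raise DomainError("Q_max must be strictly positive")


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for every optimizable parameter, (lower, upper) per entry.

    Defaults are the published clinical ranges; the compression-to-ventilation
    ratio has no published range and defaults to [5, 100], which brackets the
    conventional 15:2 and 30:2 practice and the above-30 ratios the model
    favors early in CPR.  ``Q_max`` defaults to the 700–1100 mL/min range
    used by the patient-group sweep; :meth:`table_preset` gives the
    alternative 400–1000 mL/min tabulated range.
    """

    T: tuple[float, float] = (0.132, 0.134)
    t: tuple[float, float] = (0.008, 0.012)
    x: tuple[float, float] = (5.0, 100.0)
    v_t: tuple[float, float] = (600.0, 1000.0)
    f_I_O2: tuple[float, float] = (0.13, 0.19)
    f_I_CO2: tuple[float, float] = (0.0002, 0.0006)
    Q_max: tuple[float, float] = (700.0, 1100.0)

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if lo > hi:
                raise DomainError(f"bounds for {f.name}: lower {lo} > upper {hi}")

    @classmethod
    def table_preset(cls) -> "ParameterBounds":
        """Bounds with the tabulated 400–1000 mL/min ``Q_max`` range."""
        return cls(Q_max=(400.0, 1000.0))

    def rescuer_box(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in RESCUER_PARAM_NAMES}

    def midpoint_rescuer(self, x: Optional[float] = None) -> RescuerParams:
        """Rescuer parameters at the midpoint of every bound.

        ``x`` may be overridden; the conventional ratio 30 is a common
        nominal start.
        """
        vals = {name: 0.5 * sum(getattr(self, name)) for name in RESCUER_PARAM_NAMES}
        if x is not None:
            vals["x"] = x
        return RescuerParams(**vals)


class ModelVariant(str, enum.Enum):
    """Selectable formula variant for the delivery closed form.

    ``AS_PRINTED``
        The published closed form, verbatim: the CO₂ delivery numerator
        carries ``s_O2`` and ``f_I_O2`` and both expressions imply a
        ventilation rate R = 1/t.  Default, for faithfulness.
    ``CORRECTED_CO2``
        Same structure with the CO₂ numerator symbols swapped to the CO₂
        quantities (``s_CO2``, ``f_I_CO2``).
    ``EXPLICIT_R``
        Full composition D = Q̄·ΔC with the ventilation rate computed as
        R = 1/(x·t + T), one breath per compression-plus-ventilation cycle.
    """

    AS_PRINTED = "as_printed"
    CORRECTED_CO2 = "corrected_co2"
    EXPLICIT_R = "explicit_R"

    @classmethod
    def coerce(cls, value: "ModelVariant | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(v.value for v in cls)
            raise DomainError(f"unknown model variant {value!r}; expected one of {valid}") from None


@dataclass(frozen=True)
class DeliverySnapshot:
    """All intermediate and final model outputs for one parameter set.

    ``R`` is populated only for the ``explicit_R`` variant, where the
    ventilation rate is an explicit model quantity; the closed-form variants
    leave it ``None``.
    """

    Q_bar: float
    f_A_O2: float
    f_A_CO2: float
    delta_C_O2: float
    delta_C_CO2: float
    D_O2: float
    D_CO2: float
    D_total: float
    variant: ModelVariant
    R: Optional[float] = None


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def mean_blood_flow(patient: PatientParams, rescuer: RescuerParams) -> float:
    """Mean blood flow during CPR, Q̄ = Q_max·x/(T/t + x), in mL/min.

    Flow is generated only by compressions: it is 0 at x = 0, strictly
    increasing in x, and approaches Q_max as x → ∞.
    """
    if rescuer.t <= 0:
        raise DomainError("compression time t must be strictly positive")
    return patient.Q_max * rescuer.x / (rescuer.T / rescuer.t + rescuer.x)


def ventilation_rate(rescuer: RescuerParams) -> float:
    """Average ventilation rate R = 1/(x·t + T), breaths per minute.

    One ventilation is delivered per full compression-plus-ventilation
    cycle, whose duration is x compressions of length t plus one
    ventilation pause of length T.
    """
    cycle = rescuer.x * rescuer.t + rescuer.T
    if cycle <= 0:
        raise DomainError("cycle duration x*t + T must be strictly positive")
    return 1.0 / cycle


def alveolar_fractions(
    rescuer: RescuerParams,
    constants: ModelConstants,
    Q_bar: float,
    R: float,
) -> tuple[float, float]:
    """Alveolar (= end-tidal) O₂ and CO₂ fractions from the steady-state balance.

    f_A_O2 = (v_t−v_d)·R·f_I_O2 / [(v_t−v_d)·R + Q̄·s_O2]
    f_A_CO2 = (v_t−v_d)·R·f_I_CO2 / [(v_t−v_d)·R − Q̄·s_CO2]

    Raises :class:`SingularityError` when perfusive CO₂ uptake Q̄·s_CO2
    reaches the effective alveolar ventilation (v_t−v_d)·R, where the CO₂
    balance has no steady state.
    """
    va = rescuer.v_t - constants.v_d
    if va <= 0:
        raise DomainError("tidal volume v_t must exceed dead space v_d")
    if R <= 0:
        raise DomainError("ventilation rate R must be strictly positive")
    vent = va * R
    co2_den = vent - Q_bar * constants.s_CO2
    if co2_den <= 0:
        raise SingularityError(
            "perfusion exceeds effective alveolar ventilation: "
            f"(v_t-v_d)*R = {vent:.6g} <= Q_bar*s_CO2 = {Q_bar * constants.s_CO2:.6g}"
        )
    f_A_O2 = vent * rescuer.f_I_O2 / (vent + Q_bar * constants.s_O2)
    f_A_CO2 = vent * rescuer.f_I_CO2 / co2_den
    return f_A_O2, f_A_CO2


def delta_concentrations(
    f_A_O2: float, f_A_CO2: float, constants: ModelConstants
) -> tuple[float, float]:
    """Blood-gas concentration changes in the linear dissociation-curve range.

    ΔC_O2 = s_O2·f_A_O2 and ΔC_CO2 = s_CO2·f_A_CO2, mL gas per mL blood.
    """
    if not (0.0 <= f_A_O2 <= 1.0 and 0.0 <= f_A_CO2 <= 1.0):
        raise DomainError("alveolar fractions must lie in [0, 1]")
    return constants.s_O2 * f_A_O2, constants.s_CO2 * f_A_CO2


def _closed_form_deliveries(
    Q_max, T, t, x, v_t, f_I_O2, f_I_CO2, v_d, s_O2, s_CO2, corrected: bool
):
    """Closed-form (D_O2, D_CO2, co2_denominator); array-safe.

    Shared by the scalar path and the vectorized grid oracle so that both
    evaluate the same expression.  The CO₂ denominator is returned so the
    scalar path can raise on singularity while the array path masks.
    """
    ratio = T / t + x
    va = v_t - v_d
    d_o2 = Q_max * s_O2 * x * va * f_I_O2 / (ratio * va + t * x * Q_max * s_O2)
    co2_den = ratio * va - t * x * Q_max * s_CO2
    if corrected:
        co2_num = Q_max * s_CO2 * x * va * f_I_CO2
    else:
        co2_num = Q_max * s_O2 * x * va * f_I_O2
    with np.errstate(divide="ignore", invalid="ignore"):
        d_co2 = co2_num / co2_den
    return d_o2, d_co2, co2_den


def blood_gas_delivery(
    patient: PatientParams,
    rescuer: RescuerParams,
    constants: ModelConstants = ModelConstants(),
    variant: ModelVariant | str = ModelVariant.AS_PRINTED,
) -> DeliverySnapshot:
    """Evaluate the full delivery model at one parameter set.

    Returns a :class:`DeliverySnapshot` with mean flow, alveolar fractions,
    concentration changes, the two deliveries and their sum.  The closed-form
    variants (``as_printed``, ``corrected_co2``) evaluate the published
    expressions directly and back out the alveolar fractions from
    f_A = D/(Q̄·s); the ``explicit_R`` variant composes D = Q̄·ΔC from the
    sub-operations with R = 1/(x·t + T).
    """
    variant = ModelVariant.coerce(variant)
    if rescuer.v_t <= constants.v_d:
        raise DomainError("tidal volume v_t must exceed dead space v_d")

    q_bar = mean_blood_flow(patient, rescuer)

    if variant is ModelVariant.EXPLICIT_R:
        r = ventilation_rate(rescuer)
        f_a_o2, f_a_co2 = alveolar_fractions(rescuer, constants, q_bar, r)
        dc_o2, dc_co2 = delta_concentrations(f_a_o2, f_a_co2, constants)
        d_o2 = q_bar * dc_o2
        d_co2 = q_bar * dc_co2
        return DeliverySnapshot(
            Q_bar=q_bar, R=r, f_A_O2=f_a_o2, f_A_CO2=f_a_co2,
            delta_C_O2=dc_o2, delta_C_CO2=dc_co2,
            D_O2=d_o2, D_CO2=d_co2, D_total=d_o2 + d_co2, variant=variant,
        )

    corrected = variant is ModelVariant.CORRECTED_CO2
    d_o2, d_co2, co2_den = _closed_form_deliveries(
        patient.Q_max, rescuer.T, rescuer.t, rescuer.x, rescuer.v_t,
        rescuer.f_I_O2, rescuer.f_I_CO2,
        constants.v_d, constants.s_O2, constants.s_CO2, corrected,
    )
    if co2_den <= 0:
        raise SingularityError(
            "CO2 balance denominator (T/t + x)(v_t - v_d) - t*x*Q_max*s_CO2 "
            f"= {co2_den:.6g} is nonpositive"
        )
    d_o2 = float(d_o2)
    d_co2 = float(d_co2)
    # Back out alveolar fractions from D = Q̄·s·f_A; at zero flow (x = 0)
    # the alveolar gas equals the inspired gas.
    if q_bar > 0:
        f_a_o2 = d_o2 / (q_bar * constants.s_O2)
        f_a_co2 = d_co2 / (q_bar * constants.s_CO2)
    else:
        f_a_o2, f_a_co2 = rescuer.f_I_O2, rescuer.f_I_CO2
    dc_o2, dc_co2 = constants.s_O2 * f_a_o2, constants.s_CO2 * f_a_co2
    return DeliverySnapshot(
        Q_bar=q_bar, R=None, f_A_O2=f_a_o2, f_A_CO2=f_a_co2,
        delta_C_O2=dc_o2, delta_C_CO2=dc_co2,
        D_O2=d_o2, D_CO2=d_co2, D_total=d_o2 + d_co2, variant=variant,
    )


def weighted_total_delivery(
    snapshot: DeliverySnapshot, w_O2: float = 1.0, w_CO2: float = 1.0
) -> float:
    """Differentially weighted total delivery w_O2·D_O2 + w_CO2·D_CO2, mL/min.

    Equals ``snapshot.D_total`` at unit weights.
    """
    if w_O2 < 0 or w_CO2 < 0:
        raise DomainError("delivery weights must be nonnegative")
    return w_O2 * snapshot.D_O2 + w_CO2 * snapshot.D_CO2


def validate_domain(
    patient: PatientParams,
    rescuer: "RescuerParams | dict[str, float]",
    constants: ModelConstants = ModelConstants(),
    variant: ModelVariant | str = ModelVariant.AS_PRINTED,
) -> list[str]:
    """Report every violated model precondition, empty iff evaluation succeeds.

    Each violation names the offending parameter(s) and the condition.
    ``rescuer`` may be a :class:`RescuerParams` or a plain mapping of the six
    raw values, so that candidates too invalid to construct the type (e.g.
    ``t = 0``) can still be diagnosed.  Purely a reporting operation: never
    raises.
    """
    variant = ModelVariant.coerce(variant)
    vals = rescuer.as_dict() if isinstance(rescuer, RescuerParams) else dict(rescuer)
    T, t, x = vals["T"], vals["t"], vals["x"]
    v_t, f_i_o2, f_i_co2 = vals["v_t"], vals["f_I_O2"], vals["f_I_CO2"]

    violations: list[str] = []
    if t <= 0:
        violations.append(f"t: compression time must be > 0 (got {t})")
    if T < 0:
        violations.append(f"T: ventilation time must be >= 0 (got {T})")
    if x < 0:
        violations.append(f"x: ratio must be >= 0 (got {x})")
    if not 0.0 <= f_i_o2 <= 1.0:
        violations.append(f"f_I_O2: must lie in [0, 1] (got {f_i_o2})")
    if not 0.0 <= f_i_co2 <= 1.0:
        violations.append(f"f_I_CO2: must lie in [0, 1] (got {f_i_co2})")
    if patient.Q_max <= 0:
        violations.append(f"Q_max: must be > 0 (got {patient.Q_max})")
    if v_t <= constants.v_d:
        violations.append(
            f"v_t: tidal volume {v_t} must exceed dead space v_d={constants.v_d}"
        )
    if violations:
        return violations
    try:
        blood_gas_delivery(patient, RescuerParams(**vals), constants, variant)
    except SingularityError as exc:
        violations.append(f"x, v_t, t, Q_max: CO2 singularity — {exc}")
    except DomainError as exc:  # pragma: no cover - defensive
        violations.append(str(exc))
    return violations
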