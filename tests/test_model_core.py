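"""Unit and property tests of the gas-exchange delivery model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpropt import (
    DomainError,
    ModelConstants,
    ModelVariant,
    ParameterBounds,
    PatientParams,
    RescuerParams,
    SingularityError,
    alveolar_fractions,
    blood_gas_delivery,
    delta_concentrations,
    mean_blood_flow,
    validate_domain,
    ventilation_rate,
    weighted_total_delivery,
)
from conftest import EXPECTED_D_CO2_AS_PRINTED, EXPECTED_D_CO2_CORRECTED, EXPECTED_D_O2

ALL_VARIANTS = list(ModelVariant)


def make_rescuer(**overrides):
    base = dict(T=0.133, t=0.01, x=30.0, v_t=800.0, f_I_O2=0.16, f_I_CO2=0.0004)
    base.update(overrides)
    return RescuerParams(**base)


class TestMeanBloodFlow:
    @pytest.mark.parametrize(
        "q_max, x, expected",
        [
            (1000.0, 30.0, 1000.0 * 30.0 / 43.3),
            (1000.0, 0.0, 0.0),
            (750.0, 0.0, 0.0),
        ],
    )
    def test_hand_evaluated_values(self, q_max, x, expected):
        q = mean_blood_flow(PatientParams(q_max), make_rescuer(x=x))
        assert q == pytest.approx(expected, rel=1e-12)

    def test_large_ratio_asymptote_approaches_q_max(self):
        q = mean_blood_flow(PatientParams(1000.0), make_rescuer(x=1e6))
        assert q == pytest.approx(1000.0, rel=1e-4)
        assert q < 1000.0

    def test_strictly_increasing_in_ratio_and_bounded(self):
        patient = PatientParams(1000.0)
        xs = np.linspace(0.0, 150.0, 100)
        flows = [mean_blood_flow(patient, make_rescuer(x=x)) for x in xs]
        assert all(b > a for a, b in zip(flows, flows[1:]))
        assert all(f < patient.Q_max for f in flows)


class TestVentilationRate:
    @pytest.mark.parametrize(
        "x, t, T, expected",
        [
            (30.0, 0.01, 0.133, 1.0 / 0.433),
            (0.0, 0.01, 0.133, 1.0 / 0.133),
            (15.0, 0.012, 0.133, 1.0 / 0.313),
        ],
    )
    def test_one_breath_per_cycle(self, x, t, T, expected):
        assert ventilation_rate(make_rescuer(x=x, t=t, T=T)) == pytest.approx(
            expected, rel=1e-12
        )


class TestAlveolarFractions:
    def test_hand_evaluated_steady_state(self, constants):
        r = make_rescuer()
        q_bar = 1000.0 * 30.0 / 43.3
        rate = 1.0 / 0.433
        f_o2, f_co2 = alveolar_fractions(r, constants, q_bar, rate)
        vent = 650.0 * rate
        assert f_o2 == pytest.approx(vent * 0.16 / (vent + q_bar * 1.5), rel=1e-12)
        assert f_co2 == pytest.approx(vent * 0.0004 / (vent - q_bar * 0.8), rel=1e-12)
        # spot values from the pre-build evaluation
        assert f_o2 == pytest.approx(0.09455, abs=5e-5)
        assert f_co2 == pytest.approx(6.34e-4, abs=5e-6)

    def test_zero_perfusion_gives_inspired_fractions(self, constants):
        r = make_rescuer()
        assert alveolar_fractions(r, constants, 0.0, 2.3) == pytest.approx(
            (0.16, 0.0004), rel=1e-14
        )

    def test_perfusion_dominating_ventilation_is_singular(self, constants):
        r = make_rescuer(v_t=160.0)  # effective ventilation 10*R << Q_bar*s_CO2
        with pytest.raises(SingularityError):
            alveolar_fractions(r, constants, 692.84, 2.309)

    def test_tidal_volume_below_dead_space_is_domain_error(self, constants):
        with pytest.raises(DomainError):
            alveolar_fractions(make_rescuer(v_t=100.0), constants, 10.0, 2.3)


class TestDeltaConcentrations:
    @pytest.mark.parametrize(
        "f_o2, f_co2, expected",
        [
            (0.0945, 0.0, (1.5 * 0.0945, 0.0)),
            (0.0, 0.0, (0.0, 0.0)),
            (0.0, 6.34e-4, (0.0, 0.8 * 6.34e-4)),
        ],
    )
    def test_linear_dissociation_range(self, constants, f_o2, f_co2, expected):
        got = delta_concentrations(f_o2, f_co2, constants)
        assert got == pytest.approx(expected, rel=1e-12)


class TestBloodGasDelivery:
    def test_reference_scenario_as_printed(self, reference_patient, reference_rescuer):
        snap = blood_gas_delivery(reference_patient, reference_rescuer)
        assert snap.D_O2 == pytest.approx(EXPECTED_D_O2, rel=1e-12)
        assert snap.D_CO2 == pytest.approx(EXPECTED_D_CO2_AS_PRINTED, rel=1e-12)
        assert snap.D_total == pytest.approx(snap.D_O2 + snap.D_CO2, rel=1e-12)

    def test_reference_scenario_corrected_co2(self, reference_patient, reference_rescuer):
        snap = blood_gas_delivery(
            reference_patient, reference_rescuer, variant="corrected_co2"
        )
        assert snap.D_CO2 == pytest.approx(EXPECTED_D_CO2_CORRECTED, rel=1e-12)

    def test_corrected_variant_keeps_oxygen_delivery_identical(
        self, reference_patient, reference_rescuer
    ):
        a = blood_gas_delivery(reference_patient, reference_rescuer, variant="as_printed")
        b = blood_gas_delivery(reference_patient, reference_rescuer, variant="corrected_co2")
        assert a.D_O2 == b.D_O2

    def test_explicit_r_composes_flow_times_concentration(
        self, reference_patient, reference_rescuer, constants
    ):
        snap = blood_gas_delivery(
            reference_patient, reference_rescuer, variant="explicit_R"
        )
        q_bar = mean_blood_flow(reference_patient, reference_rescuer)
        rate = ventilation_rate(reference_rescuer)
        f_o2, f_co2 = alveolar_fractions(reference_rescuer, constants, q_bar, rate)
        dc = delta_concentrations(f_o2, f_co2, constants)
        assert snap.R == pytest.approx(rate)
        assert snap.D_O2 == pytest.approx(q_bar * dc[0], rel=1e-12)
        assert snap.D_CO2 == pytest.approx(q_bar * dc[1], rel=1e-12)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_zero_compressions_deliver_nothing(self, reference_patient, variant):
        snap = blood_gas_delivery(reference_patient, make_rescuer(x=0.0), variant=variant)
        assert snap.D_O2 == 0.0 and snap.D_CO2 == 0.0 and snap.D_total == 0.0
        assert snap.Q_bar == 0.0

    @pytest.mark.parametrize("variant", [ModelVariant.AS_PRINTED, ModelVariant.CORRECTED_CO2])
    def test_dead_space_limit_kills_both_deliveries(self, reference_patient, variant):
        """Both delivery numerators scale with v_t - v_d.  The CO2
        denominator also vanishes in that limit, so the feasible approach
        scales the compression ratio down with the effective tidal volume;
        oxygen delivery vanishes along any approach."""
        prev_o2 = math.inf
        for eps in (10.0, 1.0, 0.1, 0.01):
            snap = blood_gas_delivery(
                reference_patient, make_rescuer(v_t=150.0 + eps, x=0.05 * eps),
                variant=variant,
            )
            assert snap.D_O2 < prev_o2
            assert snap.D_O2 < eps and abs(snap.D_CO2) < eps
            prev_o2 = snap.D_O2
        # oxygen delivery alone needs no rescaling: its denominator limit
        # stays positive
        d = [
            blood_gas_delivery(
                reference_patient, make_rescuer(v_t=150.0 + eps, x=5.0, t=0.008),
                variant=variant,
            ).D_O2
            if (0.133 / 0.008 + 5.0) * eps > 0.008 * 5.0 * 1000.0 * 0.8
            else 0.0
            for eps in (100.0, 50.0, 40.0)
        ]
        assert d[0] > d[1] > d[2]

    def test_singular_co2_denominator_raises(self):
        # high ratio, minimal ventilation, strong perfusion
        with pytest.raises(SingularityError):
            blood_gas_delivery(
                PatientParams(1100.0),
                make_rescuer(v_t=151.0, x=100.0, t=0.012),
            )

    def test_unknown_variant_rejected(self, reference_patient, reference_rescuer):
        with pytest.raises(DomainError):
            blood_gas_delivery(reference_patient, reference_rescuer, variant="bogus")


@st.composite
def valid_inputs(draw):
    b = ParameterBounds()
    vals = {
        name: draw(st.floats(*getattr(b, name), allow_nan=False))
        for name in ("T", "t", "x", "v_t", "f_I_O2", "f_I_CO2")
    }
    q_max = draw(st.floats(400.0, 1100.0))
    return PatientParams(q_max), RescuerParams(**vals)


class TestSnapshotInvariants:
    @settings(max_examples=150, derandomize=True)
    @given(valid_inputs(), st.sampled_from(ALL_VARIANTS))
    def test_fraction_bracketing_flow_bound_and_total(self, inputs, variant):
        """At every feasible point: f_A_O2 <= f_I_O2, f_A_CO2 >= f_I_CO2,
        0 <= Q_bar < Q_max, and D_total is the sum of the deliveries."""
        patient, rescuer = inputs
        try:
            snap = blood_gas_delivery(patient, rescuer, variant=variant)
        except SingularityError:
            return
        assert 0.0 <= snap.Q_bar < patient.Q_max
        assert snap.f_A_O2 <= rescuer.f_I_O2 + 1e-12
        assert snap.f_A_CO2 >= rescuer.f_I_CO2 - 1e-15
        assert snap.D_total == pytest.approx(snap.D_O2 + snap.D_CO2, rel=1e-12)
        assert all(
            math.isfinite(v)
            for v in (snap.Q_bar, snap.f_A_O2, snap.f_A_CO2, snap.D_O2, snap.D_CO2)
        )


class TestWeightedTotalDelivery:
    def test_projection_and_unit_weights(self, reference_patient, reference_rescuer):
        snap = blood_gas_delivery(reference_patient, reference_rescuer)
        assert weighted_total_delivery(snap, 1, 1) == pytest.approx(snap.D_total)
        assert weighted_total_delivery(snap, 0, 0) == 0.0
        assert weighted_total_delivery(snap, 1, 0) == snap.D_O2

    def test_negative_weight_rejected(self, reference_patient, reference_rescuer):
        snap = blood_gas_delivery(reference_patient, reference_rescuer)
        with pytest.raises(DomainError):
            weighted_total_delivery(snap, -1.0, 1.0)


class TestValidateDomain:
    def test_nominal_midpoints_are_clean(self):
        rescuer = ParameterBounds().midpoint_rescuer(x=30.0)
        for variant in ALL_VARIANTS:
            assert validate_domain(PatientParams(900.0), rescuer, variant=variant) == []

    def test_low_tidal_volume_named(self):
        out = validate_domain(PatientParams(900.0), make_rescuer(v_t=100.0))
        assert len(out) == 1 and "v_t" in out[0] and "dead space" in out[0]

    def test_zero_compression_time_named_from_raw_mapping(self):
        raw = make_rescuer().as_dict() | {"t": 0.0}
        out = validate_domain(PatientParams(900.0), raw)
        assert len(out) == 1 and out[0].startswith("t:")

    def test_singularity_reported_not_raised(self):
        out = validate_domain(
            PatientParams(1100.0), make_rescuer(v_t=151.0, x=100.0, t=0.012)
        )
        assert len(out) == 1 and "singularity" in out[0]


class TestConstruction:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t=0.0),
            dict(t=-0.01),
            dict(T=-1.0),
            dict(x=-5.0),
            dict(v_t=0.0),
            dict(f_I_O2=1.5),
            dict(f_I_CO2=-0.1),
        ],
    )
    def test_invalid_rescuer_values_rejected(self, kwargs):
        with pytest.raises(DomainError):
            make_rescuer(**kwargs)

    def test_invalid_constants_and_patient_rejected(self):
        with pytest.raises(DomainError):
            ModelConstants(v_d=0.0)
        with pytest.raises(DomainError):
            PatientParams(0.0)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(DomainError):
            ParameterBounds(T=(0.2, 0.1))
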