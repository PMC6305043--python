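import pytest

from cpropt import (
    ModelConstants,
    PatientParams,
    RescuerParams,
    SweepConfig,
    run_sweep,
)

# Hand-evaluated closed-form values for the reference scenario
# (Q_max=1000, x=30, T=0.133, t=0.01, v_t=800, f_I_O2=0.16, f_I_CO2=0.0004,
# default constants), frozen before implementation:
#   D_O2  = 4,680,000 / 28,595
#   D_CO2 = 4,680,000 / 27,905   (published closed form)
#   D_CO2 = 6,240 / 27,905       (CO2-corrected numerator)
EXPECTED_D_O2 = 4_680_000 / 28_595
EXPECTED_D_CO2_AS_PRINTED = 4_680_000 / 27_905
EXPECTED_D_CO2_CORRECTED = 6_240 / 27_905


@pytest.fixture
def constants():
    return ModelConstants()


@pytest.fixture
def reference_rescuer():
    """The worked-example rescuer parameter set."""
    return RescuerParams(T=0.133, t=0.01, x=30.0, v_t=800.0, f_I_O2=0.16, f_I_CO2=0.0004)


@pytest.fixture
def reference_patient():
    return PatientParams(Q_max=1000.0)


@pytest.fixture(scope="session")
def default_sweep():
    """One full patient-group sweep at the default settings, shared across
    tests that inspect its outcomes (expensive enough to run once)."""
    return run_sweep(SweepConfig(seeds=(0,)))
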