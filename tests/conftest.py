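import pytest

from rbcredox import (
    ProtocolConfig,
    build_default_model,
    evaluate_subject,
    load_reference_patients,
)


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def cfg():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def reference_patients():
    return load_reference_patients()


@pytest.fixture(scope="session")
def control(reference_patients):
    return reference_patients[-1]


@pytest.fixture(scope="session")
def control_run(model, cfg, control):
    """Steady state, trajectory and indicators of the healthy control."""
    return evaluate_subject(control, model, cfg)
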