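"""Shared fixtures: bundled models and a few expensive simulations reused
across test modules (session-scoped so each runs once)."""

import pytest

import cefapbpk as cp


@pytest.fixture(scope="session")
def mouse_model():
    return cp.build_model("mouse")


@pytest.fixture(scope="session")
def rat_model():
    return cp.build_model("rat")


@pytest.fixture(scope="session")
def human_model():
    return cp.build_model("human")


@pytest.fixture(scope="session")
def human_gut(human_model):
    return cp.load_human_gut(human_model.drug)


@pytest.fixture(scope="session")
def oral_dose():
    return cp.DoseEvent("oral", 1126.5)


@pytest.fixture(scope="session")
def rat_iv_result(rat_model):
    return cp.simulate(rat_model, dose=cp.DoseEvent("iv_bolus", 0.62), t_end=24.0)


@pytest.fixture(scope="session")
def mouse_iv_result(mouse_model):
    return cp.simulate(mouse_model, dose=cp.DoseEvent("iv_bolus", 4.79), t_end=24.0)


@pytest.fixture(scope="session")
def human_oral_result(human_model, human_gut, oral_dose):
    return cp.simulate(human_model, human_gut, oral_dose, t_end=48.0)


@pytest.fixture(scope="session")
def comparison(human_model, human_gut, oral_dose):
    """Dissolution-rate experiment over the standard T85% grid."""
    from cefapbpk.calibration import compare_release_rates

    return compare_release_rates(human_model, human_gut, oral_dose)


@pytest.fixture(scope="session")
def human_oral_no_pept1_result(human_model, human_gut, oral_dose):
    return cp.simulate(
        human_model, human_gut.without_transporter(), oral_dose, t_end=48.0
    )
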