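import pytest

from c2flux.analysis import run_scenario
from c2flux.coupling import make_scenario
from c2flux.mechanistic import MechanisticParams, solve_steady_state
from c2flux.network import build_core_model

SCENARIOS = ("A", "B", "C", "D", "C4")


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def params():
    return MechanisticParams()


@pytest.fixture(scope="session")
def c3_state(params):
    return solve_steady_state(params, V_p=0.0)


@pytest.fixture(scope="session")
def scenario_results(core_model, params):
    """All five scenario pipelines, run once per session (FVA included)."""
    return {
        name: run_scenario(core_model, params, make_scenario(name))
        for name in SCENARIOS
    }
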