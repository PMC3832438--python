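import numpy as np
import pytest

from thrombolyzer.flow import FlowTrace
from thrombolyzer.synthetic import (
    DEFAULT_PK,
    DoseRegimen,
    FlowSimParams,
    simulate_flow_trace,
)


@pytest.fixture(scope="session")
def sim_params() -> FlowSimParams:
    return FlowSimParams()


@pytest.fixture(scope="session")
def trace_dose5(sim_params) -> FlowTrace:
    """Reference-regimen 5 mg/kg animal, fixed seed."""
    return simulate_flow_trace(
        None, DoseRegimen.ten_pct_bolus_infusion(5.0), sim_params, DEFAULT_PK,
        animal_id="d5", seed=42,
    )


@pytest.fixture(scope="session")
def trace_saline(sim_params) -> FlowTrace:
    return simulate_flow_trace(
        None, DoseRegimen(total_dose=0.0), sim_params, DEFAULT_PK,
        animal_id="saline", seed=42,
    )


@pytest.fixture(scope="session")
def trace_total_bolus(sim_params) -> FlowTrace:
    return simulate_flow_trace(
        None, DoseRegimen.total_bolus(5.0), sim_params, DEFAULT_PK,
        animal_id="bolus5", seed=7,
    )


def make_trace(flow, dt_s=1.0, markers=None, animal_id="t") -> FlowTrace:
    """Handmade trace from a flow array sampled at dt_s."""
    flow = np.asarray(flow, dtype=float)
    return FlowTrace(
        animal_id=animal_id,
        time_s=np.arange(flow.size) * dt_s,
        flow=flow,
        markers=markers or {},
    )
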