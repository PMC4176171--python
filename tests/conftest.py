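import pytest
from hypothesis import HealthCheck, settings

from rampkit.kinetics import (
    LaneSpec,
    NoiseSpec,
    apply_perturbation,
    default_design,
    default_rate_model,
    steady_state,
    synthesize_quant_table,
)
from rampkit.pathway import Segment, build_default_mouse_pathway
from rampkit.ramp import default_mouse_panel

settings.register_profile(
    "rampkit",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("rampkit")

#: small segment lengths for tests that do not need the real annotation;
#: mapped site coordinates (2b +58, 2c +837..857) still fit.
TOY_LENGTHS = {
    Segment.FIVE_ETS: 300,
    Segment.S18: 100,
    Segment.ITS1: 900,
    Segment.S5_8: 30,
    Segment.ITS2: 200,
    Segment.S28: 400,
    Segment.THREE_ETS: 50,
}
TOY_SITES = {"A'": 60, "A0": 200, "1": 300, "4b": 150}


@pytest.fixture(scope="session")
def graph():
    return build_default_mouse_pathway()


@pytest.fixture(scope="session")
def toy_graph():
    return build_default_mouse_pathway(TOY_LENGTHS, TOY_SITES)


@pytest.fixture(scope="session")
def panel(graph):
    return default_mouse_panel(graph)


@pytest.fixture(scope="session")
def model(graph):
    return default_rate_model(graph)


def paired_table(model, perturbation=None, noise=NoiseSpec(), seed=0, replicates=1):
    """Synthetic table with ref/kd lane pairs for each replicate."""
    ref = steady_state(model)
    kd = steady_state(apply_perturbation(model, perturbation)) if perturbation else ref
    lanes, states = {}, {}
    for rep in range(1, replicates + 1):
        exp = f"E{rep}"
        lanes[2 * rep - 1] = LaneSpec(f"ref-{exp}", exp, "reference")
        lanes[2 * rep] = LaneSpec(f"kd-{exp}", exp, "knockdown")
        states[f"ref-{exp}"] = ref
        states[f"kd-{exp}"] = kd
    return synthesize_quant_table(states, default_design(lanes), noise, seed=seed)
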