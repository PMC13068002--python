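import numpy as np
import pytest

from celltrap.hydraulics import TrapArrayDesign
from celltrap.pipeline import analyze_stack
from celltrap.synth import ScenarioConfig, generate_ground_truth, render_timelapse

MIXED_OCCUPANCY = (
    [(1, 1)] * 10 + [(0, 1)] * 6 + [(1, 0)] * 6 + [(0, 0)] * 6 + [(2, 1)] * 2 + [(1, 2)] * 2
)


def make_scenario(seed=7, rotation=0.0, **overrides):
    """32-trap mixed-cohort scenario used across the pipeline tests."""
    kwargs = dict(
        design=TrapArrayDesign(stages=3),
        occupancy=list(MIXED_OCCUPANCY),
        death_prob={"1:1": 0.5, "1:2": 0.3, "2:1": 0.3, "multiplet": 0.3},
        rotation_deg=rotation,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def mixed_fixture():
    """Rendered + fully analyzed mixed-cohort stack (shared, read-only)."""
    scenario = make_scenario(seed=7)
    truth = generate_ground_truth(scenario)
    stack = render_timelapse(truth, scenario)
    series, flags, result = analyze_stack(stack, scenario.design)
    return {
        "scenario": scenario,
        "truth": truth,
        "stack": stack,
        "series": series,
        "flags": flags,
        "result": result,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
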