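import numpy as np
import pytest

from ssepat import (
    FluidParams,
    SystemParams,
    design_batch,
    motion_timeline,
    randomize_speeds,
    simulate_print_run,
)


@pytest.fixture(scope="session")
def system():
    return SystemParams()


@pytest.fixture(scope="session")
def fluid():
    return FluidParams()


@pytest.fixture(scope="session")
def quiet_system():
    """Noise- and friction-free system for closed-form comparisons."""
    return SystemParams(noise_sd=0.0, friction_force=0.0)


@pytest.fixture(scope="session")
def batch_run(system, fluid):
    """One full simulated 60+10-printlet batch shared across PAT tests."""
    batch, text = design_batch()
    text, assignment = randomize_speeds(text, seed=3)
    timeline = motion_timeline(text)
    trace = simulate_print_run(fluid, system, timeline, seed=3)
    return {
        "batch": batch,
        "gcode": text,
        "assignment": assignment,
        "timeline": timeline,
        "trace": trace,
    }
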