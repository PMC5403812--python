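import numpy as np
import pytest

from glucotrace.tracer_simulator import (InfusionSegment, MealEvent, Protocol,
                                         Subject, build_params, simulate)


@pytest.fixture(scope="session")
def subject70():
    return Subject(weight=70.0, height=175.0, sex="male", age=28.0)


@pytest.fixture(scope="session")
def params70(subject70):
    return build_params(subject70)


@pytest.fixture(scope="session")
def fed_protocol(subject70):
    """A one-day primed infusion with two unlabeled meals and follow-up."""
    return Protocol(
        subject=subject70,
        infusions=(InfusionSegment(0.0, 24.0, 2.7, prime=4.6),),
        meals=(MealEvent(time=8.0, cho=75.0), MealEvent(time=13.0, cho=60.0)),
        horizon=48.0)


@pytest.fixture(scope="session")
def fed_trajectory(fed_protocol, params70):
    grid = np.arange(0.0, 48.001, 0.05)
    return simulate(fed_protocol, params70, grid)
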