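import pytest

from nanofrac import (
    MotionParams,
    PlateSpec,
    ScheduleParams,
    build_schedule,
    plan_motion,
)


@pytest.fixture
def plate():
    return PlateSpec()


@pytest.fixture
def default_schedule(plate):
    """The canonical run: 40 fractions -> 8 wells round-robin at 1 min."""
    return build_schedule(ScheduleParams(), plate)


@pytest.fixture
def default_plan(default_schedule, plate):
    return plan_motion(default_schedule, plate, MotionParams())
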