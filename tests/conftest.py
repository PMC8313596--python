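import numpy as np
import pytest

from sacstep import (
    ArrayGeometry,
    StaircaseState,
    build_experiment_plan,
    default_race_parameters,
    simulate_subject,
)


@pytest.fixture
def geometry():
    return ArrayGeometry()


@pytest.fixture
def race_params():
    return default_race_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_dataset(geometry, race_params):
    """One simulated subject on a 2-session plan, fixed seed."""
    rng = np.random.default_rng(11)
    plan = build_experiment_plan(2, 60, (0.30, 0.40, 0.30), geometry, rng)
    return simulate_subject(race_params, plan, StaircaseState.from_ms(100.0), rng)


@pytest.fixture
def paper_plan(geometry):
    rng = np.random.default_rng(7)
    return build_experiment_plan(4, 60, (0.30, 0.40, 0.30), geometry, rng)
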