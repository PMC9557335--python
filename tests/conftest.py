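import numpy as np
import pytest

from treadscore import (
    SyntheticPoseConfig,
    align_to_schedule,
    build_standard_schedule,
    compute_components,
    filter_likelihood,
    normalize_to_box,
    simulate_pose_session,
)


@pytest.fixture(scope="session")
def schedule():
    return build_standard_schedule()


def prepared_session(skill: float, seed: int, schedule, **cfg_kwargs):
    """Simulate, QC-filter, normalize and align one session."""
    cfg = SyntheticPoseConfig(skill=skill, seed=seed, **cfg_kwargs)
    session, truth = simulate_pose_session(cfg, schedule)
    session = filter_likelihood(session)
    session = normalize_to_box(session)
    session = align_to_schedule(session, schedule)
    return session, truth


@pytest.fixture(scope="session")
def expert_components(schedule):
    session, _ = prepared_session(1.0, 11, schedule)
    return compute_components(session, schedule)


@pytest.fixture(scope="session")
def novice_components(schedule):
    session, _ = prepared_session(0.0, 11, schedule)
    return compute_components(session, schedule)
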