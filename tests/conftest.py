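"""Shared fixtures: one simulated session with its regressor machinery.

Expensive objects are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from lrspectrum.task import (AgentParams, BehaviorSession, TaskSchedule,
                             make_schedule, simulate_agent)
from lrspectrum.value import compute_value_traces
from lrspectrum.regressors import (CANONICAL_LR30, build_design_matrix,
                                   build_regressor_bank)
from lrspectrum.simulate import make_nuisance


@pytest.fixture(scope="session")
def demo_session() -> BehaviorSession:
    sched = make_schedule("stable_first", 60, seed=5)
    return simulate_agent(sched, AgentParams(agent_lr=0.3,
                                             inverse_temperature=5.0), seed=7)


@pytest.fixture(scope="session")
def demo_traces30(demo_session):
    return compute_value_traces(demo_session, CANONICAL_LR30)


@pytest.fixture(scope="session")
def demo_bank30(demo_session, demo_traces30):
    return build_regressor_bank(demo_session, demo_traces30)


@pytest.fixture(scope="session")
def demo_nuisance(demo_session):
    return make_nuisance(demo_session.n_volumes, seed=42)


@pytest.fixture(scope="session")
def demo_design(demo_session, demo_nuisance):
    return build_design_matrix(demo_session, nuisance=demo_nuisance)


def make_manual_session(R_A, choices=None, TR=3.0) -> BehaviorSession:
    """Hand-built session with the given coupled outcomes (timing synthetic)."""
    R_A = np.asarray(R_A, dtype=int)
    n = len(R_A)
    if choices is None:
        choices = np.zeros(n, dtype=int)
    choices = np.asarray(choices, dtype=int)
    R = np.where(choices == 0, R_A, 1 - R_A)
    t = 20.0 * np.arange(n)
    sched = TaskSchedule(
        p_reward_A=np.full(n, 0.75), magnitude_A=np.full(n, 50),
        magnitude_B=np.full(n, 50),
        subsession_label=np.array(["stable"] * n), order="stable_first")
    n_volumes = int(np.ceil((t[-1] + 18.0) / TR))
    return BehaviorSession(schedule=sched, choices=choices, R=R, R_A=R_A,
                           chosen_magnitude=np.full(n, 50.0),
                           decision_onset=t + 1.0, response_time=t + 7.0,
                           outcome_onset=t + 12.0, TR=TR,
                           n_volumes=n_volumes, seed=0)
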