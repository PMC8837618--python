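import numpy as np
import pytest
from hypothesis import settings

from retroval.agents import AgentParams, RatingModel, simulate_session
from retroval.task import SessionLog, TaskConfig, TrialRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_config():
    return TaskConfig(n_trials=64, block_len=32)


@pytest.fixture(scope="session")
def sim_session(config):
    return simulate_session(
        AgentParams(alpha=0.4, lam=0.7, omega=0.6, beta=5.0, pi=0.3),
        RatingModel(rule="MBdQ"),
        config,
        seed=123,
        subject_id="s0",
    )


def build_trial(
    t,
    colour=0,
    transition="common",
    reward=1,
    shape=None,
    rated_shape=None,
    rating_raw=None,
    s2_chosen_shape=None,
    aborted=False,
    attention=False,
):
    """Hand-build a consistent TrialRecord for oracle tests.

    The second-stage state follows from colour and transition; offered shapes
    default to (shape, (shape+1) % 5).
    """
    if shape is None:
        shape = colour
    s2_state = colour if transition == "common" else 1 - colour
    if s2_chosen_shape is None:
        s2_chosen_shape = 2 * s2_state
    offered = (shape, (shape + 1) % 5)
    colours = (colour, 1 - colour)
    if aborted:
        return TrialRecord(
            t=t, offered_shapes=offered, offered_colours=colours, aborted=True
        )
    return TrialRecord(
        t=t,
        offered_shapes=offered,
        offered_colours=colours,
        chosen_colour=colour,
        chosen_shape=shape,
        chosen_side="left",
        transition=transition,
        s2_state=s2_state,
        s2_offered_shapes=(2 * s2_state, 2 * s2_state + 1),
        s2_chosen_shape=s2_chosen_shape,
        reward=reward,
        attention_probe=attention,
        rated_shape=rated_shape,
        rating_raw=rating_raw,
    )


def build_session(trials, subject_id="hand", group="explicit", config=None):
    return SessionLog(
        subject_id=subject_id,
        group=group,
        config=config or TaskConfig(),
        trials=list(trials),
    )


@pytest.fixture
def hand_stay_session():
    """8-trial log with hand-counted stay cells.

    colours  [0,0,1,1,0,0,0,1], transitions [c,r,c,c,r,c,r,c],
    rewards  [1,0,0,1,1,1,0,0] give stay cells
    CR=2/3, CU=1, RR=1, RU=0 by direct enumeration.
    """
    colours = [0, 0, 1, 1, 0, 0, 0, 1]
    transitions = ["common", "rare", "common", "common", "rare", "common", "rare", "common"]
    rewards = [1, 0, 0, 1, 1, 1, 0, 0]
    trials = [
        build_trial(t, colour=c, transition=tr, reward=r)
        for t, (c, tr, r) in enumerate(zip(colours, transitions, rewards))
    ]
    return build_session(trials)
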