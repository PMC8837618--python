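"""Generative structure of the adapted two-stage decision task.

The task: on each trial the participant chooses one of two coloured stage-1
stimuli.  Colour alone determines the transition — each colour leads to one of
two second-stage states with probability ``p_common`` (0.7 by default) and to
the other state otherwise.  Each second-stage state offers a choice between two
grey shapes; exactly one of the four grey shapes pays reward with probability
``p_reward_high`` (0.8), all others with ``p_reward_low`` (0.2), and the
identity of the best shape is redrawn every ``block_len`` (32) trials.  The
stage-1 stimuli additionally carry one of five outcome-irrelevant shapes; at
the end of most trials one of these shapes is probed for a subjective value
rating.  This module defines the task configuration, the per-trial record and
session container, and the schedule / transition / reward sampling primitives
shared by the simulator and the analysis code.

Conventions: colours, states and shapes are 0-based integer ids.  Colour ``c``
canonically (commonly) leads to state ``c``; state ``s`` offers stage-2 shapes
``2s`` and ``2s + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "SessionLog",
    "Schedule",
    "make_schedule",
    "sample_transition",
    "sample_reward",
    "common_destination",
    "ScheduleError",
]


class ScheduleError(ValueError):
    """Raised when the task constraints cannot be satisfied."""


def common_destination(colour: int) -> int:
    """Canonical (common-transition) second-stage state of a stage-1 colour."""
    return colour


@dataclass
class TaskConfig:
    """All generative constants of the task.

    Defaults reproduce the published design: 256 trials in 32-trial reward
    blocks, 70/30 transitions, 0.8/0.2 reward probabilities, five irrelevant
    stage-1 shapes, no ratings on the first 10 trials, attention probes on
    exactly half of trials.
    """

    n_trials: int = 256
    block_len: int = 32
    p_common: float = 0.7
    p_reward_high: float = 0.8
    p_reward_low: float = 0.2
    n_colours: int = 2
    n_stage2_states: int = 2
    n_stage2_shapes: int = 4
    n_shapes: int = 5
    rating_warmup: int = 10
    attention_fraction: float = 0.5
    stage1_timeout_s: float = 4.0
    p_abort: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if not self.p_reward_high > self.p_reward_low:
            raise ValueError("p_reward_high must exceed p_reward_low")
        if self.n_trials % self.block_len != 0:
            raise ValueError("n_trials must be a multiple of block_len")
        if not self.rating_warmup < self.n_trials:
            raise ValueError("rating_warmup must be smaller than n_trials")
        if self.n_colours != 2 or self.n_stage2_states != 2 or self.n_stage2_shapes != 4:
            raise ValueError("task structure requires 2 colours, 2 states, 4 stage-2 shapes")
        if not 0.0 <= self.p_abort < 1.0:
            raise ValueError("p_abort must be in [0, 1)")

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_len

    def with_(self, **kw) -> "TaskConfig":
        return replace(self, **kw)


@dataclass
class TrialRecord:
    """One trial of a session.  Optional fields are ``None`` when absent
    (aborted trial, or no rating probe on this trial)."""

    t: int
    offered_shapes: tuple  # (left, right) irrelevant-shape ids
    offered_colours: tuple  # (left, right) colour ids
    chosen_colour: Optional[int] = None
    chosen_shape: Optional[int] = None
    chosen_side: Optional[str] = None  # "left" / "right"
    transition: Optional[str] = None  # "common" / "rare"
    s2_state: Optional[int] = None
    s2_offered_shapes: Optional[tuple] = None  # (left, right) stage-2 shape ids
    s2_chosen_shape: Optional[int] = None
    reward: Optional[int] = None
    attention_probe: bool = False
    attention_correct: Optional[bool] = None
    rated_shape: Optional[int] = None
    rating_raw: Optional[float] = None
    aborted: bool = False


@dataclass
class SessionLog:
    """Ordered trial records for one subject — the unit of all analysis."""

    subject_id: str
    group: str  # "explicit" / "implicit"
    config: TaskConfig
    trials: List[TrialRecord] = field(default_factory=list)
    block_schedule: Sequence[int] = ()  # per-block best stage-2 shape id

    def usable_trials(self) -> List[TrialRecord]:
        return [tr for tr in self.trials if not tr.aborted]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class Schedule:
    """Pre-drawn, choice-independent structure of a session.

    Everything that does not depend on the participant's choices is scheduled
    up front: the offered shape pairs and their colour/side assignment, the
    attention flags (exactly half the trials), the rated-shape assignment and
    the per-block best stage-2 shape.  Stage-2 display order is pre-drawn per
    trial for both possible states.
    """

    config: TaskConfig
    shape_left: np.ndarray
    shape_right: np.ndarray
    colour_left: np.ndarray
    colour_right: np.ndarray
    attention: np.ndarray  # bool
    rated_shape: np.ndarray  # int, -1 when no probe
    s2_order_flip: np.ndarray  # bool: display stage-2 pair reversed
    block_best: np.ndarray  # per-block best stage-2 shape id

    def offered_shapes(self, t: int) -> tuple:
        return (int(self.shape_left[t]), int(self.shape_right[t]))

    def best_shape(self, t: int) -> int:
        return int(self.block_best[t // self.config.block_len])


def make_schedule(config: TaskConfig, rng_seed: int) -> Schedule:
    """Draw the full choice-independent schedule for one session.

    Offered shape pairs are drawn uniformly from the shapes not offered on the
    previous trial (so consecutive offers are disjoint); colours and sides are
    randomised per trial; attention flags are an exact half-split; the rated
    shape is drawn uniformly from the shapes offered on neither the current
    nor the previous trial, with no probe during the warm-up trials.
    """
    config.validate()
    if config.n_shapes < 2 * 2 + 1:
        raise ScheduleError(
            f"n_shapes={config.n_shapes} cannot satisfy disjoint consecutive "
            "offers plus a ratable shape (need >= 5)"
        )
    rng = np.random.default_rng(rng_seed)
    T = config.n_trials

    shape_left = np.empty(T, dtype=int)
    shape_right = np.empty(T, dtype=int)
    colour_left = np.empty(T, dtype=int)
    colour_right = np.empty(T, dtype=int)
    rated = np.full(T, -1, dtype=int)
    prev_pair: set = set()
    all_shapes = set(range(config.n_shapes))
    for t in range(T):
        candidates = sorted(all_shapes - prev_pair)
        pair = rng.choice(candidates, size=2, replace=False)
        rng.shuffle(pair)
        shape_left[t], shape_right[t] = pair
        cl = int(rng.integers(config.n_colours))
        colour_left[t], colour_right[t] = cl, 1 - cl
        if t >= config.rating_warmup:
            excluded = set(pair) | prev_pair
            eligible = sorted(all_shapes - excluded)
            if not eligible:
                raise ScheduleError("no shape eligible for rating probe")
            rated[t] = int(rng.choice(eligible))
        prev_pair = set(int(s) for s in pair)

    n_att = int(round(config.attention_fraction * T))
    attention = np.zeros(T, dtype=bool)
    attention[rng.permutation(T)[:n_att]] = True

    s2_flip = rng.integers(2, size=T).astype(bool)
    block_best = rng.integers(config.n_stage2_shapes, size=config.n_blocks)
    return Schedule(
        config=config,
        shape_left=shape_left,
        shape_right=shape_right,
        colour_left=colour_left,
        colour_right=colour_right,
        attention=attention,
        rated_shape=rated,
        s2_order_flip=s2_flip,
        block_best=block_best,
    )


def sample_transition(chosen_colour: int, config: TaskConfig, rng: np.random.Generator):
    """Sample the second-stage state reached from a chosen colour.

    Returns ``(transition, s2_state)`` where ``transition`` is ``"common"``
    with probability ``p_common`` (landing in the colour's canonical state)
    and ``"rare"`` otherwise.
    """
    if rng.random() < config.p_common:
        return "common", common_destination(chosen_colour)
    return "rare", 1 - common_destination(chosen_colour)


def sample_reward(
    s2_chosen_shape: int,
    block_best_shape: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward: ``p_reward_high`` for the block's best shape, else
    ``p_reward_low``."""
    p = config.p_reward_high if s2_chosen_shape == block_best_shape else config.p_reward_low
    return int(rng.random() < p)


def state_shapes(state: int) -> tuple:
    """The two stage-2 shapes offered by a second-stage state."""
    return (2 * state, 2 * state + 1)
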