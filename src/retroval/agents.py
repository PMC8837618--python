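"""Synthetic agents: hybrid model-free / model-based choosers plus a
configurable ratings-generation model.

The chooser is the classic hybrid of a SARSA(λ) model-free learner and a
forward-planning model-based learner with five free parameters: learning rate
α, eligibility/discount λ, mixing weight ω, decision precision β and choice
perseverance π.  Stage-1 choice utilities are ``β·Q_net(c) + π·[c == previous
choice]`` with ``Q_net = ω·Q_mb + (1−ω)·Q_mf``; stage-2 choices use β over the
offered pair's cached values.

Ratings come from a latent value per outcome-irrelevant stage-1 shape: on each
completed trial the *chosen* shape's latent value is nudged by
``alpha_rating × RPE`` for one of the four candidate prediction errors (or not
at all), and probed ratings are the latent value mapped linearly onto the raw
rating scale plus Gaussian noise, clipped at the scale bounds.  Which RPE
trains the latent values is the generative ground truth that the downstream
stepwise analysis tries to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .task import (
    Schedule,
    SessionLog,
    TaskConfig,
    TrialRecord,
    make_schedule,
    sample_reward,
    sample_transition,
    state_shapes,
)
from .rpe import RULES, plan_values, trial_rpes

__all__ = [
    "AgentParams",
    "RatingModel",
    "QState",
    "ParamDistribution",
    "choose_stage1",
    "choose_stage2",
    "update_model_free",
    "plan_model_based",
    "simulate_session",
    "generate_cohort",
]

P_ATTENTION_CORRECT = 0.95  # simulated recall accuracy on attention probes


@dataclass
class AgentParams:
    """The five free parameters of the hybrid choice model."""

    alpha: float = 0.5  # learning rate, both stages
    lam: float = 0.6  # eligibility / temporal discount
    omega: float = 0.5  # model-based weight in the stage-1 mixture
    beta: float = 5.0  # decision precision (inverse temperature)
    pi: float = 0.2  # perseverance bonus for the previous colour

    def validate(self) -> None:
        for name in ("alpha", "lam", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (self.beta >= 0.0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        if not math.isfinite(self.pi):
            raise ValueError("pi must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam, self.omega, self.beta, self.pi])


@dataclass
class RatingModel:
    """Generative model of the shape-rating probes.

    ``rule`` names the RPE that trains the latent shape values (one of
    ``TDE_S1, TDE_S2, MFdQ, MBdQ``) or ``"none"`` for pure noise ratings.
    Latent values live in [0, 1] (initialised at 0.5) and are mapped linearly
    onto ``scale`` — raw rating units are screen pixels, matching the visual
    analogue scale the exclusion thresholds are defined on.
    """

    rule: str = "MBdQ"
    alpha_rating: float = 0.3
    noise_sd: float = 40.0
    scale: Tuple[float, float] = (0.0, 400.0)

    def validate(self) -> None:
        if self.rule not in RULES + ("none",):
            raise ValueError(f"unknown rating rule {self.rule!r}")
        if not 0.0 <= self.alpha_rating <= 1.0:
            raise ValueError("alpha_rating must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.scale[1] > self.scale[0]:
            raise ValueError("scale must be (min, max) with max > min")

    def map_to_scale(self, v: float) -> float:
        lo, hi = self.scale
        return lo + v * (hi - lo)


@dataclass
class QState:
    """Latent values carried across trials by an agent (and by the replay
    in :mod:`retroval.fitting`)."""

    q_mf_s1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q_s2: np.ndarray = field(default_factory=lambda: np.zeros(4))
    v_shape: np.ndarray = field(default_factory=lambda: np.full(5, 0.5))

    def q_mb_s1(self, p_common: float) -> np.ndarray:
        return plan_values(self.q_s2, p_common)

    def copy(self) -> "QState":
        return QState(self.q_mf_s1.copy(), self.q_s2.copy(), self.v_shape.copy())


def plan_model_based(qs: QState, p_common: float) -> np.ndarray:
    """Forward-planning stage-1 values from the current stage-2 values."""
    return qs.q_mb_s1(p_common)


def stage1_choice_probs(
    qs: QState, params: AgentParams, prev_chosen_colour: Optional[int], p_common: float
) -> np.ndarray:
    """Softmax probabilities over the two colours under the hybrid rule."""
    q_net = params.omega * qs.q_mb_s1(p_common) + (1.0 - params.omega) * qs.q_mf_s1
    u = params.beta * q_net
    if prev_chosen_colour is not None:
        u = u.copy()
        u[prev_chosen_colour] += params.pi
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def choose_stage1(
    qs: QState,
    params: AgentParams,
    prev_chosen_colour: Optional[int],
    rng: np.random.Generator,
    p_common: float = 0.7,
) -> int:
    """Sample a stage-1 colour from the hybrid softmax."""
    p = stage1_choice_probs(qs, params, prev_chosen_colour, p_common)
    return int(rng.random() >= p[0])


def choose_stage2(
    qs: QState, params: AgentParams, state: int, rng: np.random.Generator
) -> int:
    """Sample a stage-2 shape: softmax with β over the state's cached values."""
    a, b = state_shapes(state)
    d = params.beta * (qs.q_s2[a] - qs.q_s2[b])
    p_a = 1.0 / (1.0 + math.exp(-d))
    return a if rng.random() < p_a else b


def update_model_free(
    qs: QState,
    chosen_colour: int,
    s2_chosen_shape: int,
    reward: float,
    params: AgentParams,
) -> QState:
    """Apply the SARSA(λ) model-free updates for one completed trial.

    The stage-1 colour is credited with the stage-2 value error (evaluated
    before the stage-2 value itself is updated) plus the λ-weighted outcome
    error; the chosen stage-2 shape absorbs the outcome error directly.
    Mutates ``qs`` in place and returns it.
    """
    a = params.alpha
    q2_old = qs.q_s2[s2_chosen_shape]
    delta1 = q2_old - qs.q_mf_s1[chosen_colour]
    delta2 = reward - q2_old
    qs.q_mf_s1[chosen_colour] += a * delta1 + a * params.lam * delta2
    qs.q_s2[s2_chosen_shape] += a * delta2
    return qs


@dataclass
class SimulationInternals:
    """Per-trial latent state exposed for replay-equivalence checks."""

    q_mf_s1: np.ndarray  # (n_usable, 2) pre-trial snapshots
    q_s2: np.ndarray  # (n_usable, 4)
    q_mb_s1: np.ndarray  # (n_usable, 2)
    v_shape: np.ndarray  # (n_usable, 5) pre-trial snapshots
    rpes: List[Tuple[float, float, float, float, int]]


def simulate_session(
    params: AgentParams,
    rating_model: RatingModel,
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    group: str = "explicit",
    return_internals: bool = False,
):
    """Simulate one complete session of the task.

    The schedule, the agent's choices and the rating noise all derive from
    ``seed``.  With ``return_internals=True`` also returns the pre-trial value
    snapshots and per-trial RPEs for equivalence testing against the fitted
    replay.
    """
    params.validate()
    rating_model.validate()
    config.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_seed, agent_seed = ss.spawn(2)
    schedule = make_schedule(config, sched_seed)
    rng = np.random.default_rng(agent_seed)

    qs = QState()
    qs.v_shape = np.full(config.n_shapes, 0.5)
    prev_colour: Optional[int] = None
    trials: List[TrialRecord] = []
    snaps_mf, snaps_s2, snaps_mb, snaps_v, rpes = [], [], [], [], []

    for t in range(config.n_trials):
        offered = schedule.offered_shapes(t)
        colours = (int(schedule.colour_left[t]), int(schedule.colour_right[t]))
        rec = TrialRecord(
            t=t,
            offered_shapes=offered,
            offered_colours=colours,
            attention_probe=bool(schedule.attention[t]),
        )
        if config.p_abort > 0 and rng.random() < config.p_abort:
            rec.aborted = True
            trials.append(rec)
            continue

        snaps_mf.append(qs.q_mf_s1.copy())
        snaps_s2.append(qs.q_s2.copy())
        snaps_mb.append(qs.q_mb_s1(config.p_common))
        snaps_v.append(qs.v_shape.copy())

        colour = choose_stage1(qs, params, prev_colour, rng, config.p_common)
        side = 0 if colours[0] == colour else 1
        rec.chosen_colour = colour
        rec.chosen_shape = offered[side]
        rec.chosen_side = "left" if side == 0 else "right"

        rec.transition, rec.s2_state = sample_transition(colour, config, rng)
        pair = state_shapes(rec.s2_state)
        if schedule.s2_order_flip[t]:
            pair = (pair[1], pair[0])
        rec.s2_offered_shapes = pair
        rec.s2_chosen_shape = choose_stage2(qs, params, rec.s2_state, rng)
        rec.reward = sample_reward(rec.s2_chosen_shape, schedule.best_shape(t), config, rng)

        if rec.attention_probe:
            rec.attention_correct = bool(rng.random() < P_ATTENTION_CORRECT)

        rpe_tuple = trial_rpes(
            qs.q_mf_s1,
            qs.q_s2,
            config.p_common,
            colour,
            rec.s2_state,
            rec.s2_chosen_shape,
            rec.reward,
        )
        rpes.append(rpe_tuple)
        if rating_model.rule != "none":
            rpe_value = dict(zip(RULES, rpe_tuple[:4]))[rating_model.rule]
            if rating_model.rule in ("MFdQ", "MBdQ"):
                # retrospective rules credit the shape that carried the colour
                # that would most likely have led here: the chosen shape on a
                # common transition, the other offered shape on a rare one
                retro_colour = rpe_tuple[4]
                side_of_retro = 0 if colours[0] == retro_colour else 1
                target_shape = offered[side_of_retro]
            else:
                target_shape = rec.chosen_shape
            qs.v_shape[target_shape] += rating_model.alpha_rating * rpe_value

        rated = int(schedule.rated_shape[t])
        if rated >= 0:
            raw = rating_model.map_to_scale(qs.v_shape[rated])
            raw += rng.normal(0.0, rating_model.noise_sd)
            lo, hi = rating_model.scale
            rec.rated_shape = rated
            rec.rating_raw = float(np.clip(raw, lo, hi))

        update_model_free(qs, colour, rec.s2_chosen_shape, rec.reward, params)
        prev_colour = colour
        trials.append(rec)

    session = SessionLog(
        subject_id=subject_id,
        group=group,
        config=config,
        trials=trials,
        block_schedule=schedule.block_best.tolist(),
    )
    if return_internals:
        internals = SimulationInternals(
            q_mf_s1=np.array(snaps_mf),
            q_s2=np.array(snaps_s2),
            q_mb_s1=np.array(snaps_mb),
            v_shape=np.array(snaps_v),
            rpes=rpes,
        )
        return session, internals
    return session


@dataclass
class ParamDistribution:
    """Independent per-parameter sampling ranges for cohort generation.

    Defaults span the plausible behavioural range: moderate learning rates
    and eligibility, the full model-based weight range, decision precision
    well away from random responding, and a mild perseverance spread.
    """

    alpha: Tuple[float, float] = (0.2, 0.8)
    lam: Tuple[float, float] = (0.2, 0.8)
    omega: Tuple[float, float] = (0.0, 1.0)
    beta: Tuple[float, float] = (2.0, 8.0)
    pi: Tuple[float, float] = (-0.3, 1.0)

    def sample(self, rng: np.random.Generator) -> AgentParams:
        u = lambda lo_hi: float(rng.uniform(*lo_hi))
        return AgentParams(
            alpha=u(self.alpha),
            lam=u(self.lam),
            omega=u(self.omega),
            beta=u(self.beta),
            pi=u(self.pi),
        )


def generate_cohort(
    n_subjects: int,
    param_distribution,
    rating_model: RatingModel,
    config: TaskConfig,
    seed: int,
    group: str = "explicit",
    subject_prefix: str = "sub",
) -> Tuple[List[SessionLog], List[AgentParams]]:
    """Simulate an independent cohort and record the generating parameters.

    ``param_distribution`` may be a :class:`ParamDistribution`, a fixed
    :class:`AgentParams` (used for every subject), or a callable
    ``rng -> AgentParams``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    param_seed, *session_seeds = ss.spawn(n_subjects + 1)
    prng = np.random.default_rng(param_seed)
    sessions, truths = [], []
    for i in range(n_subjects):
        if isinstance(param_distribution, AgentParams):
            params = replace(param_distribution)
        elif isinstance(param_distribution, ParamDistribution):
            params = param_distribution.sample(prng)
        else:
            params = param_distribution(prng)
        sess = simulate_session(
            params,
            rating_model,
            config,
            seed=session_seeds[i],
            subject_id=f"{subject_prefix}{i:03d}",
            group=group,
        )
        sessions.append(sess)
        truths.append(params)
    return sessions, truths
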