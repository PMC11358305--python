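"""Generative choice models for the multi-reward reversal tasks.

Two agents are implemented:

* **EXP** (experience-based): a Rescorla-Wagner learner. Each stimulus carries
  a subjective value ``V_i`` (drops of juice, initialized to 0 each session).
  Choice between an offered pair follows a softmax on the values with inverse
  temperature ``beta``; after each trial only the chosen stimulus's value
  moves toward the obtained reward, ``V_i <- V_i - alpha * (V_i - r_obs)``.

* **INF** (inference-based): the learner knows the association takes one of
  two fixed patterns — A: ``S_i -> i`` drops, B: ``S_i -> 6 - i`` drops — and
  carries a confidence weight ``w`` in [0, 1] that pattern A is in force
  (initialized to 0.5). Choice follows the ``w``-mixture of the two softmax
  distributions over the fixed value tables; ``w`` moves by stochastic
  gradient descent on the squared reward-prediction error,
  ``w <- clip_[0,1](w - alpha * ((w*V_A_i + (1-w)*V_B_i) - r_obs) * (V_A_i - V_B_i))``.

Both agents optionally apply a distinct learning rate on flagged
post-reversal trials, which is how chemogenetic "silencing" is emulated in
synthetic cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ContractError, ValidationError, stim_index

#: fixed value tables of the INF model, indexed 0..4 by stimulus
V_A: np.ndarray = np.arange(1.0, 6.0)        # pattern A: S_i -> i drops
V_B: np.ndarray = 6.0 - np.arange(1.0, 6.0)  # pattern B: S_i -> 6 - i drops


def _pair_softmax(v_i: float, v_j: float, beta: float) -> float:
    """P(choose i) under a two-option softmax, overflow-safe."""
    d = beta * (v_i - v_j)
    if d >= 0:
        return 1.0 / (1.0 + math.exp(-d))
    e = math.exp(d)
    return e / (1.0 + e)


@dataclass(frozen=True)
class ExpParams:
    alpha: float
    beta: float
    alpha_post: float | None = None  # used on post-reversal trials if set

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha={self.alpha} outside [0, 1]")
        if self.beta < 0.0:
            raise ValidationError(f"beta={self.beta} must be >= 0")
        if self.alpha_post is not None and not 0.0 <= self.alpha_post <= 1.0:
            raise ValidationError(f"alpha_post={self.alpha_post} outside [0, 1]")


@dataclass(frozen=True)
class InfParams:
    alpha: float
    beta: float
    alpha_post: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0.0:
            raise ValidationError(f"alpha={self.alpha} must be >= 0")
        if self.beta < 0.0:
            raise ValidationError(f"beta={self.beta} must be >= 0")


@dataclass
class ExpState:
    """Subjective values per stimulus; zeros at session start."""

    V: np.ndarray = field(default_factory=lambda: np.zeros(5))


@dataclass
class InfState:
    """Confidence that pattern A is in force; 0.5 at session start."""

    w: float = 0.5


def exp_choice_prob(state: ExpState, pair: tuple[str, str], beta: float) -> float:
    """Probability the EXP agent chooses ``pair[0]`` over ``pair[1]``."""
    if beta < 0:
        raise ValidationError(f"beta={beta} must be >= 0")
    i, j = stim_index(pair[0]), stim_index(pair[1])
    return _pair_softmax(float(state.V[i]), float(state.V[j]), beta)


def exp_update(state: ExpState, chosen: str, r_obs: int, alpha: float) -> ExpState:
    """Rescorla-Wagner update of the chosen stimulus's value only."""
    i = stim_index(chosen)
    V = state.V.copy()
    V[i] = V[i] - alpha * (V[i] - r_obs)
    return ExpState(V=V)


def inf_choice_prob(state: InfState, pair: tuple[str, str], beta: float) -> float:
    """Mixture-of-softmax probability that the INF agent chooses ``pair[0]``."""
    w = state.w
    if not 0.0 <= w <= 1.0:
        raise ValidationError(f"w={w} outside [0, 1]")
    if beta < 0:
        raise ValidationError(f"beta={beta} must be >= 0")
    i, j = stim_index(pair[0]), stim_index(pair[1])
    p_a = _pair_softmax(V_A[i], V_A[j], beta)
    p_b = _pair_softmax(V_B[i], V_B[j], beta)
    return w * p_a + (1.0 - w) * p_b


def inf_update(state: InfState, chosen: str, r_obs: int, alpha: float) -> InfState:
    """Gradient update of the pattern-A confidence weight, clipped to [0, 1]."""
    i = stim_index(chosen)
    expected = state.w * V_A[i] + (1.0 - state.w) * V_B[i]
    w = state.w - alpha * (expected - r_obs) * (V_A[i] - V_B[i])
    return InfState(w=min(1.0, max(0.0, float(w))))


class ExpAgent:
    """Generative EXP agent implementing the choose/observe contract."""

    model = "EXP"

    def __init__(self, params: ExpParams):
        self.params = params
        self.state = ExpState()

    def reset(self) -> None:
        self.state = ExpState()

    def choice_prob(self, pair: tuple[str, str]) -> float:
        return exp_choice_prob(self.state, pair, self.params.beta)

    def choose(self, pair: tuple[str, str], rng: np.random.Generator) -> str:
        p_first = self.choice_prob(pair)
        return pair[0] if rng.random() < p_first else pair[1]

    def observe(self, chosen: str, r_obs: int, *, post_reversal: bool = False) -> None:
        alpha = self.params.alpha
        if post_reversal and self.params.alpha_post is not None:
            alpha = self.params.alpha_post
        self.state = exp_update(self.state, chosen, r_obs, alpha)


class InfAgent:
    """Generative INF agent implementing the choose/observe contract."""

    model = "INF"

    def __init__(self, params: InfParams):
        self.params = params
        self.state = InfState()

    def reset(self) -> None:
        self.state = InfState()

    def choice_prob(self, pair: tuple[str, str]) -> float:
        return inf_choice_prob(self.state, pair, self.params.beta)

    def choose(self, pair: tuple[str, str], rng: np.random.Generator) -> str:
        p_first = self.choice_prob(pair)
        return pair[0] if rng.random() < p_first else pair[1]

    def observe(self, chosen: str, r_obs: int, *, post_reversal: bool = False) -> None:
        alpha = self.params.alpha
        if post_reversal and self.params.alpha_post is not None:
            alpha = self.params.alpha_post
        self.state = inf_update(self.state, chosen, r_obs, alpha)


def make_agent(model: str, params: ExpParams | InfParams) -> ExpAgent | InfAgent:
    if model.upper() == "EXP":
        if not isinstance(params, ExpParams):
            raise ContractError("EXP agent requires ExpParams")
        return ExpAgent(params)
    if model.upper() == "INF":
        if not isinstance(params, InfParams):
            raise ContractError("INF agent requires InfParams")
        return InfAgent(params)
    raise ContractError(f"unknown model {model!r}")


def simulate_choices(model, params, env, rng, **session_meta):
    """Simulate one session of the given task with a generative agent.

    ``env`` is a task spec from :mod:`revalue.task_engine`
    (``NovelTaskSpec`` or ``FamiliarTaskSpec``); the matching closed-loop
    runner is dispatched on its type. Returns the completed
    :class:`~revalue.core_io.Session`.
    """
    from . import task_engine  # local import to avoid a cycle

    agent = make_agent(model, params)
    if isinstance(env, task_engine.NovelTaskSpec):
        return task_engine.run_novel_session(env, agent, rng, **session_meta)
    if isinstance(env, task_engine.FamiliarTaskSpec):
        return task_engine.run_familiar_session(env, agent, rng, **session_meta)
    raise ContractError(f"unknown environment {type(env).__name__}")


__all__ = [
    "V_A", "V_B",
    "ExpParams", "InfParams", "ExpState", "InfState",
    "exp_choice_prob", "exp_update", "inf_choice_prob", "inf_update",
    "ExpAgent", "InfAgent", "make_agent", "simulate_choices",
]
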