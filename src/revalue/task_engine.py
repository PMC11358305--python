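"""Closed-loop simulation of the NOVEL and FAMILIAR reversal tasks.

Five stimuli are mapped bijectively onto 1-5 drops of juice under one of two
patterns: pattern A gives ``S_i -> i`` drops, pattern B is the pointwise
reversal ``S_i -> 6 - i``. The pair offered on each trial cycles through all
C(5,2) = 10 unordered pairs once per 10-trial block, independently permuted
per block, with random left/right placement.

NOVEL sessions run 90 acquisition trials under the initial pattern, then
reverse once, then run 210 more trials. FAMILIAR sessions reverse whenever
the optimal-choice rate over the trailing 30 completed trials exceeds 76%
(implemented as >= 23/30, the smallest count strictly above the threshold);
the trailing window resets at each reversal so no window spans a boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_io import (
    STIMULI,
    ContractError,
    Session,
    TrialRecord,
    ValidationError,
)

#: all C(5,2) = 10 unordered stimulus pairs, in canonical order
ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(STIMULI, 2))


@dataclass(frozen=True)
class StimulusRewardMap:
    """Bijection stimulus -> drops under one association pattern."""

    rewards: tuple[int, ...]  # drops for S1..S5
    pattern: str  # "A" or "B"

    def __post_init__(self) -> None:
        if sorted(self.rewards) != [1, 2, 3, 4, 5]:
            raise ValidationError(f"rewards {self.rewards} not a bijection onto 1..5")
        if self.pattern not in ("A", "B"):
            raise ValidationError(f"pattern {self.pattern!r} not in {{A, B}}")

    def reward(self, stim: str) -> int:
        return self.rewards[int(stim[1:]) - 1]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(STIMULI, self.rewards))


def pattern_a() -> StimulusRewardMap:
    return StimulusRewardMap(rewards=(1, 2, 3, 4, 5), pattern="A")


def pattern_b() -> StimulusRewardMap:
    return StimulusRewardMap(rewards=(5, 4, 3, 2, 1), pattern="B")


def reverse_map(m: StimulusRewardMap) -> StimulusRewardMap:
    """Reverse the association: r drops become 6 - r; pattern label flips."""
    return StimulusRewardMap(
        rewards=tuple(6 - r for r in m.rewards),
        pattern="B" if m.pattern == "A" else "A",
    )


@dataclass(frozen=True)
class NovelTaskSpec:
    """90 acquisition trials, one forced reversal, 210 post-reversal trials."""

    n_acquisition: int = 90
    n_post: int = 210

    def __post_init__(self) -> None:
        if self.n_acquisition < 1 or self.n_post < 1:
            raise ValidationError("trial counts must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_acquisition + self.n_post


@dataclass(frozen=True)
class FamiliarTaskSpec:
    """Fixed-length session with criterion-triggered reversals.

    ``initial_pattern`` of None means a coin flip at session start.
    """

    n_trials: int = 300
    criterion_window: int = 30
    criterion_rate: float = 0.76
    initial_pattern: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials < self.criterion_window:
            raise ValidationError("n_trials must be >= criterion_window")
        if not 0.0 < self.criterion_rate < 1.0:
            raise ValidationError("criterion_rate must be in (0, 1)")

    @property
    def criterion_count(self) -> int:
        """Smallest correct count strictly exceeding the criterion rate."""
        import math

        return math.floor(self.criterion_window * self.criterion_rate) + 1


def round_robin_pairs(rng: np.random.Generator) -> list[tuple[str, str]]:
    """One 10-trial block: every unordered pair once, sides randomized."""
    order = rng.permutation(len(ALL_PAIRS))
    block = []
    for k in order:
        a, b = ALL_PAIRS[k]
        block.append((a, b) if rng.random() < 0.5 else (b, a))
    return block


def pair_schedule(n_trials: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Round-robin schedule of ``n_trials`` pairs (blocks independently permuted)."""
    schedule: list[tuple[str, str]] = []
    while len(schedule) < n_trials:
        schedule.extend(round_robin_pairs(rng))
    return schedule[:n_trials]


def _play_trial(
    trial_index: int,
    pair: tuple[str, str],
    reward_map: StimulusRewardMap,
    agent,
    agent_rng: np.random.Generator,
    *,
    post_reversal: bool,
    reversal_boundary: bool,
) -> TrialRecord:
    left, right = pair
    choice = agent.choose(pair, agent_rng)
    if choice not in pair:
        raise ContractError(
            f"agent chose {choice!r}, not among offered pair {pair} (trial {trial_index})"
        )
    r_obs = reward_map.reward(choice)
    agent.observe(choice, r_obs, post_reversal=post_reversal)
    return TrialRecord(
        trial_index=trial_index,
        stim_left=left,
        stim_right=right,
        reward_left=reward_map.reward(left),
        reward_right=reward_map.reward(right),
        choice=choice,
        reward_obtained=r_obs,
        pattern_in_force=reward_map.pattern,
        post_reversal_flag=post_reversal,
        reversal_boundary=reversal_boundary,
    )


def run_novel_session(
    spec: NovelTaskSpec,
    agent,
    rng: np.random.Generator,
    *,
    session_id: str = "novel-0",
    subject: str = "sub-0",
    treatment: str = "none",
    rng_seed: int = 0,
) -> Session:
    """Run one NOVEL session: the reversal occurs after trial 90 regardless
    of behavior, so trial 91 is the reversal boundary."""
    task_rng, agent_rng = rng.spawn(2)
    schedule = pair_schedule(spec.n_trials, task_rng)
    reward_map = pattern_a()
    trials: list[TrialRecord] = []
    for t, pair in enumerate(schedule, start=1):
        if t == spec.n_acquisition + 1:
            reward_map = reverse_map(reward_map)
        post = t > spec.n_acquisition
        trials.append(
            _play_trial(
                t, pair, reward_map, agent, agent_rng,
                post_reversal=post,
                reversal_boundary=(t == spec.n_acquisition + 1),
            )
        )
    return Session(
        session_id=session_id, subject=subject, task="NOVEL",
        treatment=treatment, trials=trials, rng_seed=rng_seed,
    )


#: post-reversal period length of the FAMILIAR task (trials after each reversal)
FAMILIAR_POST_WINDOW = 5


def run_familiar_session(
    spec: FamiliarTaskSpec,
    agent,
    rng: np.random.Generator,
    *,
    session_id: str = "familiar-0",
    subject: str = "sub-0",
    treatment: str = "none",
    rng_seed: int = 0,
) -> Session:
    """Run one FAMILIAR session with criterion-triggered reversals.

    After each completed trial the trailing ``criterion_window`` optimal
    indicators (since the last reversal) are checked; when at least
    ``criterion_count`` of them are optimal the association reverses before
    the next trial.
    """
    task_rng, agent_rng = rng.spawn(2)
    schedule = pair_schedule(spec.n_trials, task_rng)
    if spec.initial_pattern is None:
        reward_map = pattern_a() if task_rng.random() < 0.5 else pattern_b()
    else:
        reward_map = pattern_a() if spec.initial_pattern == "A" else pattern_b()

    trials: list[TrialRecord] = []
    window: list[int] = []  # optimal indicators since last reversal
    since_reversal: int | None = None  # trials completed since last boundary
    pending_reversal = False
    for t, pair in enumerate(schedule, start=1):
        boundary = False
        if pending_reversal:
            reward_map = reverse_map(reward_map)
            window = []
            since_reversal = 0
            boundary = True
            pending_reversal = False
        post = since_reversal is not None and since_reversal < FAMILIAR_POST_WINDOW
        rec = _play_trial(
            t, pair, reward_map, agent, agent_rng,
            post_reversal=post, reversal_boundary=boundary,
        )
        trials.append(rec)
        if since_reversal is not None:
            since_reversal += 1
        window.append(1 if rec.reward_obtained > rec.reward_of_unchosen else 0)
        if (
            len(window) >= spec.criterion_window
            and sum(window[-spec.criterion_window:]) >= spec.criterion_count
        ):
            pending_reversal = True
    return Session(
        session_id=session_id, subject=subject, task="FAMILIAR",
        treatment=treatment, trials=trials, rng_seed=rng_seed,
    )


__all__ = [
    "ALL_PAIRS", "FAMILIAR_POST_WINDOW",
    "StimulusRewardMap", "pattern_a", "pattern_b", "reverse_map",
    "NovelTaskSpec", "FamiliarTaskSpec",
    "round_robin_pairs", "pair_schedule",
    "run_novel_session", "run_familiar_session",
]
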