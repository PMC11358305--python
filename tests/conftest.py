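"""Shared fixtures: session builders and an independent likelihood oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from revalue.agents import ExpParams, InfParams, make_agent
from revalue.core_io import STIMULI, Session, TrialRecord
from revalue.task_engine import (
    ALL_PAIRS,
    FamiliarTaskSpec,
    NovelTaskSpec,
    pattern_a,
    reverse_map,
    run_familiar_session,
    run_novel_session,
)


def scripted_session(
    task: str,
    pairs: list[tuple[str, str]],
    choices: list[str],
    boundaries: set[int],
    *,
    session_id: str = "scripted",
    subject: str = "sub",
    treatment: str = "none",
) -> Session:
    """Build a session from an explicit pair/choice script.

    ``boundaries`` are 1-based trial indices at which the reward pattern
    flips (pattern A in force from trial 1). Rewards and flags are derived
    from the script, so the result satisfies all data-model invariants.
    """
    reward_map = pattern_a()
    trials = []
    last_boundary = None
    for t, (pair, choice) in enumerate(zip(pairs, choices), start=1):
        boundary = t in boundaries
        if boundary:
            reward_map = reverse_map(reward_map)
            last_boundary = t
        if task == "NOVEL":
            post = last_boundary is not None
        else:
            post = last_boundary is not None and t - last_boundary < 5
        left, right = pair
        trials.append(TrialRecord(
            trial_index=t, stim_left=left, stim_right=right,
            reward_left=reward_map.reward(left), reward_right=reward_map.reward(right),
            choice=choice, reward_obtained=reward_map.reward(choice),
            pattern_in_force=reward_map.pattern,
            post_reversal_flag=post, reversal_boundary=boundary,
        ))
    session = Session(session_id=session_id, subject=subject, task=task,
                      treatment=treatment, trials=trials)
    session.validate()
    return session


def random_scripted_session(rng: np.random.Generator, n_trials: int = 20) -> Session:
    """A random valid session (random pairs/choices/boundaries) for oracles."""
    pairs = []
    for _ in range(n_trials):
        a, b = ALL_PAIRS[rng.integers(len(ALL_PAIRS))]
        pairs.append((a, b) if rng.random() < 0.5 else (b, a))
    choices = [p[int(rng.integers(2))] for p in pairs]
    if rng.random() < 0.5:
        task = "NOVEL"
        boundaries = {int(rng.integers(2, n_trials + 1))}
    else:
        task = "FAMILIAR"
        n_rev = int(rng.integers(0, 3))
        boundaries = set(
            int(b) for b in rng.choice(np.arange(2, n_trials + 1),
                                       size=min(n_rev, n_trials - 1), replace=False)
        )
    return scripted_session(task, pairs, choices, boundaries)


def oracle_negloglik(
    model: str,
    session: Session,
    alpha_other: float,
    alpha_post: float,
    beta: float,
) -> float:
    """Step-by-step likelihood recomputation, independent of the package's
    likelihood path (plain floats, naive softmax, its own mask logic)."""
    boundaries = [t.trial_index for t in session.trials if t.reversal_boundary]
    mask = []
    for t in session.trials:
        if session.task == "NOVEL":
            mask.append(any(t.trial_index >= b for b in boundaries))
        else:
            mask.append(any(b <= t.trial_index < b + 5 for b in boundaries))
    V = [0.0] * 5
    w = 0.5
    nll = 0.0
    for t, m in zip(session.trials, mask):
        i = int(t.choice[1:]) - 1
        unchosen = t.stim_right if t.choice == t.stim_left else t.stim_left
        j = int(unchosen[1:]) - 1
        if model == "EXP":
            num = math.exp(beta * V[i])
            p = num / (num + math.exp(beta * V[j]))
        else:
            va_i, va_j = i + 1.0, j + 1.0
            vb_i, vb_j = 5.0 - i, 5.0 - j
            pa = math.exp(beta * va_i) / (math.exp(beta * va_i) + math.exp(beta * va_j))
            pb = math.exp(beta * vb_i) / (math.exp(beta * vb_i) + math.exp(beta * vb_j))
            p = w * pa + (1.0 - w) * pb
        nll -= math.log(p)
        a = alpha_post if m else alpha_other
        r = float(t.reward_obtained)
        if model == "EXP":
            V[i] = V[i] - a * (V[i] - r)
        else:
            va_i, vb_i = i + 1.0, 5.0 - i
            w = w - a * ((w * va_i + (1.0 - w) * vb_i) - r) * (va_i - vb_i)
            w = min(1.0, max(0.0, w))
    return nll


@pytest.fixture(scope="session")
def exp_novel_sessions():
    """20 NOVEL sessions generated by EXP(alpha=0.15, beta=1.5), fixed seeds."""
    out = []
    for k in range(20):
        agent = make_agent("EXP", ExpParams(alpha=0.15, beta=1.5))
        rng = np.random.default_rng(1000 + k)
        out.append(run_novel_session(NovelTaskSpec(), agent, rng,
                                     session_id=f"exp-novel-{k:02d}", rng_seed=1000 + k))
    return out


@pytest.fixture(scope="session")
def inf_familiar_sessions():
    """20 FAMILIAR sessions generated by INF(alpha=0.05, beta=1.5), fixed seeds."""
    out = []
    for k in range(20):
        agent = make_agent("INF", InfParams(alpha=0.05, beta=1.5))
        rng = np.random.default_rng(2000 + k)
        out.append(run_familiar_session(FamiliarTaskSpec(), agent, rng,
                                        session_id=f"inf-familiar-{k:02d}",
                                        rng_seed=2000 + k))
    return out


def positive_experience_fixture():
    """30-trial NOVEL-like script encoding the positive worked example.

    After the reversal at trial 11 (pattern B: S1 -> 5 drops), S1 is offered
    against the 2-drop option and not chosen (trial 12), later chosen over
    the 3-drop option (trial 15, the unpredicted positive experience), and
    the next trial offering S1 is the 1-vs-5 trial 18 (evaluation). S2, the
    other high-valued option, is always chosen when offered so it yields no
    event.
    """
    pre = [(("S2", "S3"), "S2")] * 10
    poe = [
        (("S3", "S2"), "S2"),  # 11: S2 chosen whenever offered
        (("S1", "S4"), "S4"),  # 12: 5-vs-2, S1 NOT chosen
        (("S3", "S4"), "S3"),  # 13
        (("S4", "S5"), "S4"),  # 14
        (("S3", "S1"), "S1"),  # 15: 3-vs-5, S1 chosen -> positive experience
        (("S3", "S5"), "S3"),  # 16
        (("S4", "S3"), "S3"),  # 17
        (("S5", "S1"), "S1"),  # 18: 1-vs-5 -> evaluation trial (optimal)
    ] + [(("S3", "S4"), "S3"), (("S4", "S5"), "S4"), (("S3", "S5"), "S3")] * 4
    script = pre + poe
    pairs = [p for p, _ in script]
    choices = [c for _, c in script]
    return scripted_session("NOVEL", pairs, choices, {11},
                            session_id="positive-example")


def negative_experience_fixture():
    """30-trial NOVEL-like script encoding the negative worked example.

    After the reversal (pattern B: S5 -> 1 drop), S5 is offered against the
    2-drop option and not chosen (trial 12), later chosen over the 4-drop
    option (trial 15, the unpredicted negative experience), and the next
    trial offering S5 is the 1-vs-3 trial 17 (evaluation). S4, the other
    low-valued option, is always chosen when offered so it yields no event.
    """
    pre = [(("S2", "S3"), "S2")] * 10
    poe = [
        (("S4", "S3"), "S4"),  # 11: S4 chosen whenever offered
        (("S5", "S4"), "S4"),  # 12: 1-vs-2, S5 NOT chosen
        (("S3", "S2"), "S3"),  # 13
        (("S2", "S3"), "S2"),  # 14
        (("S5", "S2"), "S5"),  # 15: 1-vs-4, S5 chosen -> negative experience
        (("S2", "S3"), "S2"),  # 16
        (("S5", "S3"), "S3"),  # 17: 1-vs-3 -> evaluation trial (optimal)
    ] + [(("S2", "S3"), "S2")] * 13
    script = pre + poe
    pairs = [p for p, _ in script]
    choices = [c for _, c in script]
    return scripted_session("NOVEL", pairs, choices, {11},
                            session_id="negative-example")


def inference_trial_fixture():
    """30-trial FAMILIAR script: the first post-reversal trial offers
    (S2, S4); the trials offering (S2, S5) and (S4, S1) share a stimulus
    with it and are skipped; trial 14 offering (S1, S3) is the first
    disjoint pair — the inference trial."""
    pre = [(("S1", "S2"), "S1")] * 10
    post = [
        (("S2", "S4"), "S4"),  # 11: first post-reversal trial (suboptimal)
        (("S2", "S5"), "S2"),  # 12: shares S2 -> excluded
        (("S4", "S1"), "S1"),  # 13: shares S4 -> excluded
        (("S1", "S3"), "S1"),  # 14: disjoint -> inference trial (optimal: 5 vs 3)
    ] + [(("S2", "S3"), "S2")] * 16
    script = pre + post
    pairs = [p for p, _ in script]
    choices = [c for _, c in script]
    return scripted_session("FAMILIAR", pairs, choices, {11},
                            session_id="inference-example")


class AlwaysOptimalAgent:
    """Ideal observer: deduces the in-force pattern from each delivered
    reward, so it chooses optimally on every trial except the first trial
    after an unsignalled reversal (where its belief is one trial stale).
    Start it on sessions whose initial pattern matches ``believed``."""

    def __init__(self, believed: str = "A"):
        self.pattern = believed

    def _reward(self, stim: str) -> int:
        i = int(stim[1:])
        return i if self.pattern == "A" else 6 - i

    def choose(self, pair, rng):
        return max(pair, key=self._reward)

    def observe(self, chosen, r_obs, *, post_reversal=False):
        if int(chosen[1:]) != 3:  # S3 pays 3 drops under both patterns
            self.pattern = "A" if r_obs == int(chosen[1:]) else "B"


class RandomAgent:
    """Chance-level agent (p = 0.5 each side)."""

    def choose(self, pair, rng):
        return pair[int(rng.integers(2))]

    def observe(self, chosen, r_obs, *, post_reversal=False):
        pass
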