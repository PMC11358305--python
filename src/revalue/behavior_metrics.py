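"""Model-agnostic behavioral statistics on trial logs.

Everything here is computed directly from the choices, without reference to
any fitted model: optimal-choice rates (per trial, per 10-trial block, per
reversal phase), extraction of trials following unpredicted positive or
negative experiences, extraction of "inference" trials after FAMILIAR
reversals, and the devaluation proportion-shifted statistic.

Phase windows around a reversal: in NOVEL sessions Pre is the 90 trials
before the reversal, PoE the first 100 after, PoL the next 110; in FAMILIAR
sessions Pre/PoE/PoL are the 10 trials before and the first 5 / next 5 after
each reversal, with per-reversal means averaged across reversals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Session, TrialRecord, ValidationError

logger = logging.getLogger("revalue")

NOVEL_PRE, NOVEL_POE, NOVEL_POL = 90, 100, 110
FAMILIAR_PRE, FAMILIAR_POE, FAMILIAR_POL = 10, 5, 5


def optimal_choice_indicator(trial: TrialRecord) -> int:
    """1 iff the chosen stimulus carries the larger in-force reward."""
    return 1 if trial.reward_of_chosen > trial.reward_of_unchosen else 0


def optimal_indicators(session: Session) -> np.ndarray:
    return np.array([optimal_choice_indicator(t) for t in session.trials], dtype=float)


def block_optimal_rate(session: Session, block: int = 10) -> np.ndarray:
    """Mean optimal-choice rate per consecutive block (trailing partial dropped)."""
    ind = optimal_indicators(session)
    n_blocks = len(ind) // block
    if len(ind) % block:
        logger.warning("session %s: dropping trailing partial block of %d trial(s)",
                       session.session_id, len(ind) % block)
    return ind[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)


def _window_mean(ind: np.ndarray, start: int, stop: int) -> float:
    """Mean over 0-based half-open [start, stop), clipped to the session."""
    start = max(start, 0)
    stop = min(stop, len(ind))
    if stop <= start:
        return np.nan
    return float(ind[start:stop].mean())


def phase_rates(session: Session) -> dict[str, float]:
    """Mean optimal-choice rate in the Pre / PoE / PoL windows."""
    boundaries = [t - 1 for t in session.reversal_trials()]  # 0-based
    if not boundaries:
        raise ValidationError(f"session {session.session_id}: no reversal present")
    ind = optimal_indicators(session)
    if session.task == "NOVEL":
        b = boundaries[0]
        return {
            "Pre": _window_mean(ind, b - NOVEL_PRE, b),
            "PoE": _window_mean(ind, b, b + NOVEL_POE),
            "PoL": _window_mean(ind, b + NOVEL_POE, b + NOVEL_POE + NOVEL_POL),
        }
    # FAMILIAR: per-reversal windows, then averaged across reversals.
    # A Pre window is truncated where it would overlap the previous
    # reversal's PoE+PoL trials.
    per_phase: dict[str, list[float]] = {"Pre": [], "PoE": [], "PoL": []}
    for k, b in enumerate(boundaries):
        pre_lo = b - FAMILIAR_PRE
        if k > 0:
            prev_post_end = boundaries[k - 1] + FAMILIAR_POE + FAMILIAR_POL
            if pre_lo < prev_post_end:
                logger.warning(
                    "session %s: Pre window before reversal at trial %d truncated "
                    "(short inter-reversal interval)", session.session_id, b + 1)
                pre_lo = prev_post_end
        per_phase["Pre"].append(_window_mean(ind, pre_lo, b))
        per_phase["PoE"].append(_window_mean(ind, b, b + FAMILIAR_POE))
        per_phase["PoL"].append(_window_mean(ind, b + FAMILIAR_POE,
                                             b + FAMILIAR_POE + FAMILIAR_POL))
    return {ph: float(np.nanmean(vals)) if not all(np.isnan(v) for v in vals) else np.nan
            for ph, vals in per_phase.items()}


@dataclass(frozen=True)
class ExperienceEvent:
    """One unpredicted positive/negative experience and its evaluation trial.

    All indices are 1-based trial indices. ``evaluation_trial`` is None when
    the option is never offered again within the search window.
    """

    option: str
    sign: str  # "positive" | "negative"
    nonchoice_trial: int
    event_trial: int
    evaluation_trial: int | None
    evaluation_optimal: int | None


def _poe_range(session: Session) -> tuple[int, int]:
    """0-based half-open PoE window of a NOVEL-like session."""
    boundaries = [t - 1 for t in session.reversal_trials()]
    if not boundaries:
        raise ValidationError(f"session {session.session_id}: no reversal present")
    b = boundaries[0]
    return b, min(b + NOVEL_POE, session.n_trials)


def extract_experience_events(
    session: Session,
    sign: str,
    scope: str = "poe",
) -> tuple[list[ExperienceEvent], float]:
    """Extract trials following unpredicted positive/negative experiences.

    A positive experience is a single choice of a high-valued option (4 or 5
    drops under the in-force map) that follows an earlier presentation where
    that option was offered but not chosen; a negative experience is the
    mirror image with low-valued options (1 or 2 drops). The evaluation
    trial is the next PoE trial offering that option after the experience;
    the returned rate is the mean optimal-choice indicator over evaluation
    trials. One event per option (the first qualifying choice).

    ``scope`` places the non-choice/choice search either inside the PoE
    window only (``"poe"``, default) or anywhere in the post-reversal period
    (``"post"``); evaluation trials always lie in PoE.
    """
    if sign not in ("positive", "negative"):
        raise ValidationError(f"sign {sign!r} not in {{positive, negative}}")
    if scope not in ("poe", "post"):
        raise ValidationError(f"scope {scope!r} not in {{poe, post}}")
    poe_lo, poe_hi = _poe_range(session)
    search_hi = poe_hi if scope == "poe" else session.n_trials
    trials = session.trials
    wanted = (4, 5) if sign == "positive" else (1, 2)
    # in-force rewards are post-reversal ones throughout the search window
    events: list[ExperienceEvent] = []
    eval_inds: list[int] = []
    for option in sorted({s for t in trials[poe_lo:search_hi] for s in t.pair}):
        value = None
        for t in trials[poe_lo:search_hi]:
            if option in t.pair:
                value = t.reward_left if t.stim_left == option else t.reward_right
                break
        if value not in wanted:
            continue
        nonchoice = event = None
        for pos in range(poe_lo, search_hi):
            t = trials[pos]
            if option not in t.pair:
                continue
            if nonchoice is None:
                if t.choice != option:
                    nonchoice = pos
            elif t.choice == option:
                event = pos
                break
        if event is None:
            continue
        evaluation = None
        for pos in range(event + 1, poe_hi):
            if option in trials[pos].pair:
                evaluation = pos
                break
        ev_opt = optimal_choice_indicator(trials[evaluation]) if evaluation is not None else None
        events.append(ExperienceEvent(
            option=option, sign=sign,
            nonchoice_trial=nonchoice + 1, event_trial=event + 1,
            evaluation_trial=None if evaluation is None else evaluation + 1,
            evaluation_optimal=ev_opt,
        ))
        if ev_opt is not None:
            eval_inds.append(ev_opt)
    rate = float(np.mean(eval_inds)) if eval_inds else np.nan
    return events, rate


@dataclass(frozen=True)
class InferenceExtraction:
    """Per-reversal first post-reversal trial and its inference trial."""

    first_trial: int  # 1-based
    inference_trial: int | None
    first_optimal: int
    inference_optimal: int | None


def extract_inference_trials(
    session: Session,
) -> tuple[list[InferenceExtraction], float, float]:
    """Find, per FAMILIAR reversal, the earliest later trial whose offered
    pair shares no stimulus with the first post-reversal trial's pair.

    Returns the per-reversal records plus the mean optimal-choice rate on
    inference trials and on first post-reversal trials. A reversal with no
    disjoint trial before the next reversal contributes only a first trial.
    """
    boundaries = [t - 1 for t in session.reversal_trials()]
    if not boundaries:
        raise ValidationError(f"session {session.session_id}: no reversal present")
    trials = session.trials
    out: list[InferenceExtraction] = []
    for k, b in enumerate(boundaries):
        stop = boundaries[k + 1] if k + 1 < len(boundaries) else session.n_trials
        first_pair = set(trials[b].pair)
        inference = None
        for pos in range(b + 1, stop):
            if not first_pair & set(trials[pos].pair):
                inference = pos
                break
        out.append(InferenceExtraction(
            first_trial=b + 1,
            inference_trial=None if inference is None else inference + 1,
            first_optimal=optimal_choice_indicator(trials[b]),
            inference_optimal=(None if inference is None
                               else optimal_choice_indicator(trials[inference])),
        ))
    inf_vals = [e.inference_optimal for e in out if e.inference_optimal is not None]
    inf_rate = float(np.mean(inf_vals)) if inf_vals else np.nan
    first_rate = float(np.mean([e.first_optimal for e in out]))
    return out, inf_rate, first_rate


@dataclass(frozen=True)
class DevaluationCounts:
    """Choice counts for two foods at baseline (N) and after devaluation (D)."""

    f1n: int
    f1d: int
    f2n: int
    f2d: int

    def __post_init__(self) -> None:
        for v in (self.f1n, self.f1d, self.f2n, self.f2d):
            if v < 0:
                raise ValidationError("devaluation counts must be non-negative")


def proportion_shifted(c: DevaluationCounts) -> float:
    """((F1N - F1D) + (F2N - F2D)) / (F1N + F2N)."""
    denom = c.f1n + c.f2n
    if denom == 0:
        raise ValidationError("baseline counts F1N + F2N must be positive")
    return ((c.f1n - c.f1d) + (c.f2n - c.f2d)) / denom


def metrics_table(sessions) -> pd.DataFrame:
    """Per-session summary: phase rates, experience-event rates and (for
    FAMILIAR sessions) inference-trial rates."""
    rows = []
    for s in sessions:
        row = {"session_id": s.session_id, "subject": s.subject, "task": s.task,
               "treatment": s.treatment, "n_trials": s.n_trials,
               "n_reversals": len(s.reversal_trials()),
               "optimal_rate": float(optimal_indicators(s).mean())}
        row.update(phase_rates(s))
        if s.task == "NOVEL":
            _, row["positive_event_rate"] = extract_experience_events(s, "positive")
            _, row["negative_event_rate"] = extract_experience_events(s, "negative")
        else:
            _, inf_rate, first_rate = extract_inference_trials(s)
            row["inference_rate"] = inf_rate
            row["first_trial_rate"] = first_rate
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "optimal_choice_indicator", "optimal_indicators", "block_optimal_rate",
    "phase_rates", "ExperienceEvent", "extract_experience_events",
    "InferenceExtraction", "extract_inference_trials",
    "DevaluationCounts", "proportion_shifted", "metrics_table",
]
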