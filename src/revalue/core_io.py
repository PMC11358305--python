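"""Trial-log data model and CSV I/O.

The canonical on-disk format is a tidy CSV with one completed trial per row.
Session metadata (subject, task, treatment, seed) is repeated on every row so
that a single file round-trips losslessly. Stimulus ids are the strings
``S1``..``S5``; rewards are integer drop counts 1-5; trials are indexed from 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("revalue")

STIMULI: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
DROPS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: column order of the tidy trial log (deterministic for bit-stable writes)
CSV_COLUMNS: tuple[str, ...] = (
    "session_id",
    "subject",
    "task",
    "treatment",
    "rng_seed",
    "trial_index",
    "stim_left",
    "stim_right",
    "reward_left",
    "reward_right",
    "choice",
    "reward_obtained",
    "pattern_in_force",
    "post_reversal_flag",
    "reversal_boundary",
)


class RevalueError(Exception):
    """Base class for package errors."""


class FormatError(RevalueError):
    """A trial-log file does not have the documented layout."""


class ValidationError(RevalueError):
    """A session or trial violates a data-model invariant."""


class ContractError(RevalueError):
    """An agent violated the choose/observe contract."""


class FittingError(RevalueError):
    """Maximum-likelihood estimation failed on all starts."""


def stim_index(stim: str) -> int:
    """0-based index of a stimulus id ('S1' -> 0)."""
    try:
        idx = int(stim[1:]) - 1
    except (TypeError, ValueError, IndexError):
        raise ValidationError(f"not a stimulus id: {stim!r}") from None
    if not (stim.startswith("S") and 0 <= idx < 5):
        raise ValidationError(f"not a stimulus id: {stim!r}")
    return idx


@dataclass(frozen=True)
class TrialRecord:
    """One completed choice trial.

    ``pattern_in_force`` names which of the two stimulus-reward association
    patterns (A: S_i -> i drops; B: S_i -> 6-i drops) governed the trial.
    ``reversal_boundary`` marks the first trial governed by a newly reversed
    pattern; ``post_reversal_flag`` marks the task-specific post-reversal
    period (all later trials in a NOVEL session, the five trials after each
    reversal in a FAMILIAR session).
    """

    trial_index: int
    stim_left: str
    stim_right: str
    reward_left: int
    reward_right: int
    choice: str
    reward_obtained: int
    pattern_in_force: str
    post_reversal_flag: bool
    reversal_boundary: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.stim_left, self.stim_right)

    @property
    def reward_of_chosen(self) -> int:
        return self.reward_left if self.choice == self.stim_left else self.reward_right

    @property
    def reward_of_unchosen(self) -> int:
        return self.reward_right if self.choice == self.stim_left else self.reward_left

    @property
    def unchosen(self) -> str:
        return self.stim_right if self.choice == self.stim_left else self.stim_left

    def validate(self) -> None:
        if self.stim_left == self.stim_right:
            raise ValidationError(
                f"trial {self.trial_index}: identical stimuli offered ({self.stim_left})"
            )
        stim_index(self.stim_left), stim_index(self.stim_right)
        if self.reward_left == self.reward_right:
            raise ValidationError(
                f"trial {self.trial_index}: identical rewards offered ({self.reward_left})"
            )
        for r in (self.reward_left, self.reward_right):
            if r not in DROPS:
                raise ValidationError(f"trial {self.trial_index}: reward {r} not in 1..5")
        if self.choice not in (self.stim_left, self.stim_right):
            raise ValidationError(
                f"trial {self.trial_index}: choice {self.choice!r} was not offered"
            )
        if self.reward_obtained != self.reward_of_chosen:
            raise ValidationError(
                f"trial {self.trial_index}: reward_obtained={self.reward_obtained} "
                f"does not equal reward of chosen side ({self.reward_of_chosen})"
            )
        if self.pattern_in_force not in ("A", "B"):
            raise ValidationError(
                f"trial {self.trial_index}: pattern {self.pattern_in_force!r} not in {{A,B}}"
            )


@dataclass
class Session:
    """An ordered sequence of completed trials plus metadata."""

    session_id: str
    subject: str
    task: str  # "NOVEL" | "FAMILIAR"
    treatment: str
    trials: list[TrialRecord] = field(default_factory=list)
    rng_seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def reversal_trials(self) -> list[int]:
        """1-based trial indices where ``reversal_boundary`` is set."""
        return [t.trial_index for t in self.trials if t.reversal_boundary]

    def validate(self) -> None:
        if self.task not in ("NOVEL", "FAMILIAR"):
            raise ValidationError(f"session {self.session_id}: unknown task {self.task!r}")
        prev_pattern = None
        for pos, trial in enumerate(self.trials, start=1):
            if trial.trial_index != pos:
                raise ValidationError(
                    f"session {self.session_id}: trial_index {trial.trial_index} at "
                    f"position {pos} (must be contiguous from 1)"
                )
            try:
                trial.validate()
            except ValidationError as err:
                raise ValidationError(f"session {self.session_id}: {err}") from None
            if (
                prev_pattern is not None
                and trial.pattern_in_force != prev_pattern
                and not trial.reversal_boundary
            ):
                raise ValidationError(
                    f"session {self.session_id}: trial {trial.trial_index}: pattern "
                    "changed without a reversal boundary"
                )
            prev_pattern = trial.pattern_in_force
        n_rev = len(self.reversal_trials())
        if self.task == "NOVEL" and n_rev != 1:
            raise ValidationError(
                f"session {self.session_id}: NOVEL session has {n_rev} reversals (expected 1)"
            )


@dataclass
class RunConfig:
    """Settings shared by the pipeline stages.

    All randomness flows from explicit seeds; no stage touches global RNG
    state.
    """

    preset: str = "ofc"
    master_seed: int = 0
    n_starts: int = 10
    out_dir: str = "revalue_out"
    n_permutations: int = 2000
    posterior_mode: str = "per_session"  # or "summed_bic"

    def validate(self) -> None:
        if self.n_starts < 1 or self.n_permutations < 1:
            raise ValidationError("n_starts and n_permutations must be positive")
        if self.master_seed < 0:
            raise ValidationError("master_seed must be non-negative")


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                (
                    s.session_id, s.subject, s.task, s.treatment, s.rng_seed,
                    t.trial_index, t.stim_left, t.stim_right, t.reward_left,
                    t.reward_right, t.choice, t.reward_obtained,
                    t.pattern_in_force, t.post_reversal_flag, t.reversal_boundary,
                )
            )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_sessions(df: pd.DataFrame, *, validate: bool = True) -> list[Session]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial log is missing column(s): {', '.join(missing)}")
    sessions: list[Session] = []
    for sid, grp in df.groupby("session_id", sort=False):
        grp = grp.sort_values("trial_index")
        meta = grp.iloc[0]
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                stim_left=str(r.stim_left),
                stim_right=str(r.stim_right),
                reward_left=int(r.reward_left),
                reward_right=int(r.reward_right),
                choice=str(r.choice),
                reward_obtained=int(r.reward_obtained),
                pattern_in_force=str(r.pattern_in_force),
                post_reversal_flag=bool(r.post_reversal_flag),
                reversal_boundary=bool(r.reversal_boundary),
            )
            for r in grp.itertuples(index=False)
        ]
        session = Session(
            session_id=str(sid),
            subject=str(meta.subject),
            task=str(meta.task),
            treatment=str(meta.treatment),
            trials=trials,
            rng_seed=int(meta.rng_seed),
        )
        if validate:
            session.validate()
        sessions.append(session)
    return sessions


def read_sessions(path: str | Path, *, validate: bool = True) -> list[Session]:
    """Read a tidy trial-log CSV into Sessions (grouped, sorted, validated)."""
    df = pd.read_csv(path)
    sessions = frame_to_sessions(df, validate=validate)
    logger.info("read %d session(s), %d trial(s) from %s",
                len(sessions), sum(s.n_trials for s in sessions), path)
    return sessions


def write_sessions(sessions: Iterable[Session], path: str | Path) -> Path:
    """Write Sessions as a tidy CSV. Byte-stable for identical inputs."""
    path = Path(path)
    df = sessions_to_frame(list(sessions))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


__all__ = [
    "STIMULI", "DROPS", "CSV_COLUMNS", "stim_index",
    "TrialRecord", "Session", "RunConfig",
    "read_sessions", "write_sessions", "sessions_to_frame", "frame_to_sessions",
    "RevalueError", "FormatError", "ValidationError", "ContractError", "FittingError",
]
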