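"""Study-shaped synthetic cohorts with known ground truth.

A cohort mirrors the layout of the chemogenetic-silencing experiments: two
subjects, a control arm ("vehicle") and a treated arm ("DCZ"), with several
sessions of one task per subject and arm. Silencing is emulated purely as a
multiplicative reduction of the generating agent's learning rate on
post-reversal trials in the treated arm; the inverse temperature is left
untouched, so any recovered beta contrast is noise.

Default generating parameters (EXP: alpha=0.15, beta=1.5 on NOVEL; INF:
alpha=0.05, beta=1.5 on FAMILIAR) are package constants chosen to produce
learning curves of the right qualitative shape — acquisition within ~90
trials on NOVEL, adaptation within a few trials after FAMILIAR reversals —
not values fitted to any animal.

Ground truth is returned as a separate table keyed by session id and is
never consumed by the fitting stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .agents import ExpParams, InfParams, make_agent
from .core_io import Session, ValidationError
from .task_engine import (
    FamiliarTaskSpec,
    NovelTaskSpec,
    run_familiar_session,
    run_novel_session,
)

EXP_DEFAULTS = {"alpha": 0.15, "beta": 1.5}
INF_DEFAULTS = {"alpha": 0.05, "beta": 1.5}

#: FAMILIAR session lengths per subject (Mk1-like and Mk2-like animals)
FAMILIAR_N_TRIALS = {"Mk1": 300, "Mk2": 400}

TREATED_LABEL = "DCZ"
CONTROL_LABEL = "vehicle"


@dataclass(frozen=True)
class CohortDesign:
    """Layout of one synthetic task cohort.

    ``effect_multiplier`` scales the post-reversal learning rate in the
    treated arm (1.0 = no silencing effect).
    """

    task: str = "NOVEL"  # "NOVEL" | "FAMILIAR"
    subjects: tuple[str, ...] = ("Mk1", "Mk2")
    treatments: tuple[str, ...] = (CONTROL_LABEL, TREATED_LABEL)
    n_sessions: int = 7  # per subject x treatment
    model: str = "EXP"
    alpha: float = EXP_DEFAULTS["alpha"]
    beta: float = EXP_DEFAULTS["beta"]
    effect_multiplier: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_multiplier <= 1.0:
            raise ValidationError(
                f"effect_multiplier={self.effect_multiplier} outside (0, 1]")
        if self.n_sessions < 1:
            raise ValidationError("n_sessions must be >= 1")
        if self.task not in ("NOVEL", "FAMILIAR"):
            raise ValidationError(f"unknown task {self.task!r}")


def novel_design(master_seed: int = 0, *, n_sessions: int = 7,
                 effect_multiplier: float = 0.5) -> CohortDesign:
    """EXP-generated NOVEL cohort (7 sessions per arm by default)."""
    return CohortDesign(task="NOVEL", model="EXP", n_sessions=n_sessions,
                        effect_multiplier=effect_multiplier,
                        master_seed=master_seed, **EXP_DEFAULTS)


def familiar_design(master_seed: int = 0, *, n_sessions: int = 6,
                    effect_multiplier: float = 0.5) -> CohortDesign:
    """INF-generated FAMILIAR cohort (6 sessions per arm by default)."""
    return CohortDesign(task="FAMILIAR", model="INF", n_sessions=n_sessions,
                        effect_multiplier=effect_multiplier,
                        master_seed=master_seed, **INF_DEFAULTS)


def preset_designs(preset: str, master_seed: int = 0) -> dict[str, CohortDesign]:
    """Named study layouts.

    ``ofc``  — silencing affects post-reversal updating in both tasks
               (7 NOVEL / 6 FAMILIAR sessions per arm);
    ``rmcd`` — effect in the NOVEL cohort only (5 sessions per arm);
    ``mdm``  — effect in the FAMILIAR cohort only (5 sessions per arm).
    """
    if preset == "ofc":
        return {
            "NOVEL": novel_design(master_seed, n_sessions=7, effect_multiplier=0.5),
            "FAMILIAR": familiar_design(master_seed + 1, n_sessions=6,
                                        effect_multiplier=0.5),
        }
    if preset == "rmcd":
        return {
            "NOVEL": novel_design(master_seed, n_sessions=5, effect_multiplier=0.5),
            "FAMILIAR": familiar_design(master_seed + 1, n_sessions=5,
                                        effect_multiplier=1.0),
        }
    if preset == "mdm":
        return {
            "NOVEL": novel_design(master_seed, n_sessions=5, effect_multiplier=1.0),
            "FAMILIAR": familiar_design(master_seed + 1, n_sessions=5,
                                        effect_multiplier=0.5),
        }
    raise ValidationError(f"unknown preset {preset!r} (expected ofc, rmcd or mdm)")


def _session_seed(master_seed: int, index: int) -> int:
    # distinct, reproducible, < 2**31
    return int((master_seed * 100003 + 7919 * index + 1) % (2**31 - 1))


def generate_cohort(design: CohortDesign) -> tuple[list[Session], pd.DataFrame]:
    """Simulate every subject x treatment x session of a design.

    Returns the sessions plus a ground-truth table (one row per session:
    generating model, learning rates actually in force on post-reversal and
    other trials, beta, seed). Pure function of the design.
    """
    sessions: list[Session] = []
    truth_rows = []
    index = 0
    for subject in design.subjects:
        for treatment in design.treatments:
            treated = treatment != CONTROL_LABEL
            mult = design.effect_multiplier if treated else 1.0
            alpha_post = design.alpha * mult
            for s in range(design.n_sessions):
                seed = _session_seed(design.master_seed, index)
                index += 1
                rng = np.random.default_rng(seed)
                sid = f"{design.task.lower()}-{subject}-{treatment}-{s:02d}"
                if design.model == "EXP":
                    params = ExpParams(alpha=design.alpha, beta=design.beta,
                                       alpha_post=None if mult == 1.0 else alpha_post)
                else:
                    params = InfParams(alpha=design.alpha, beta=design.beta,
                                       alpha_post=None if mult == 1.0 else alpha_post)
                agent = make_agent(design.model, params)
                meta = dict(session_id=sid, subject=subject, treatment=treatment,
                            rng_seed=seed)
                if design.task == "NOVEL":
                    session = run_novel_session(NovelTaskSpec(), agent, rng, **meta)
                else:
                    spec = FamiliarTaskSpec(
                        n_trials=FAMILIAR_N_TRIALS.get(subject, 300))
                    session = run_familiar_session(spec, agent, rng, **meta)
                sessions.append(session)
                truth_rows.append({
                    "session_id": sid, "subject": subject, "task": design.task,
                    "treatment": treatment, "model": design.model,
                    "alpha_other": design.alpha, "alpha_post": alpha_post,
                    "beta": design.beta, "effect_multiplier": mult, "seed": seed,
                })
    return sessions, pd.DataFrame(truth_rows)


def recovery_report(ground_truth: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Parameter-recovery summary against ground truth.

    Uses the modified-variant fits of the generating model. One row per
    treatment arm (bias and mean absolute error of alpha_post, mean beta)
    plus a ``treated-minus-control`` contrast row.
    """
    model = ground_truth["model"].iloc[0]
    sub = fits[(fits["model"] == model) & (fits["variant"] == "modified")]
    merged = ground_truth.merge(sub, on="session_id", suffixes=("_true", ""))
    if len(merged) != len(ground_truth):
        missing = set(ground_truth["session_id"]) - set(sub["session_id"])
        raise ValidationError(f"fits missing for session(s): {sorted(missing)}")
    rows = []
    arm_means = {}
    for treatment, grp in merged.groupby("treatment_true", sort=False):
        err = grp["alpha_post"] - grp["alpha_post_true"]
        rows.append({
            "treatment": treatment,
            "n_sessions": len(grp),
            "alpha_post_true": float(grp["alpha_post_true"].mean()),
            "alpha_post_hat": float(grp["alpha_post"].mean()),
            "alpha_post_bias": float(err.mean()),
            "alpha_post_mae": float(err.abs().mean()),
            "beta_hat": float(grp["beta"].mean()),
            "beta_bias": float((grp["beta"] - grp["beta_true"]).mean()),
        })
        arm_means[treatment] = (float(grp["alpha_post"].mean()), float(grp["beta"].mean()))
    if TREATED_LABEL in arm_means and CONTROL_LABEL in arm_means:
        rows.append({
            "treatment": "treated-minus-control",
            "n_sessions": len(merged),
            "alpha_post_true": np.nan,
            "alpha_post_hat": arm_means[TREATED_LABEL][0] - arm_means[CONTROL_LABEL][0],
            "alpha_post_bias": np.nan,
            "alpha_post_mae": np.nan,
            "beta_hat": arm_means[TREATED_LABEL][1] - arm_means[CONTROL_LABEL][1],
            "beta_bias": np.nan,
        })
    return pd.DataFrame(rows)


def design_to_dict(design: CohortDesign) -> dict:
    d = asdict(design)
    d["subjects"] = list(design.subjects)
    d["treatments"] = list(design.treatments)
    return d


__all__ = [
    "EXP_DEFAULTS", "INF_DEFAULTS", "FAMILIAR_N_TRIALS",
    "TREATED_LABEL", "CONTROL_LABEL",
    "CohortDesign", "novel_design", "familiar_design", "preset_designs",
    "generate_cohort", "recovery_report", "design_to_dict",
]
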