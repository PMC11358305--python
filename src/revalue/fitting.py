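"""Per-session maximum-likelihood fitting of the EXP and INF models.

Each model comes in two variants:

* ``basic`` — one learning rate ``alpha`` and inverse temperature ``beta``
  (2 free parameters);
* ``modified`` — separate learning rates for the post-reversal period
  (``alpha_post``) and all other trials (``alpha_other``), plus ``beta``
  (3 free parameters). The post-reversal period covers every trial after
  the reversal in a NOVEL session and the five trials after each reversal
  in a FAMILIAR session. ``alpha_post`` is the learning rate reported in
  downstream summaries because it isolates updating right after the
  contingencies change.

Optimization is multi-start bounded local search: a seeded Latin-hypercube
draws starting points over the box alpha in [0, 1], beta in [0, 10], each
refined with L-BFGS-B; the best converged start wins. Fits are fully
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from ._kernels import exp_nll_kernel, inf_nll_kernel
from .core_io import FittingError, Session, ValidationError, stim_index
from .task_engine import FAMILIAR_POST_WINDOW

MODELS = ("EXP", "INF")
VARIANTS = ("basic", "modified")


def post_reversal_mask(session: Session) -> np.ndarray:
    """Boolean per-trial mask of the post-reversal period.

    Recomputed from the reversal boundaries (not the stored flags): in a
    NOVEL session every trial from the boundary onward is post-reversal; in
    a FAMILIAR session the five trials starting at each boundary are,
    truncated at session end.
    """
    n = session.n_trials
    mask = np.zeros(n, dtype=np.bool_)
    boundaries = [t - 1 for t in session.reversal_trials()]  # 0-based
    if session.task == "NOVEL":
        for b in boundaries:
            mask[b:] = True
    else:
        for b in boundaries:
            mask[b : b + FAMILIAR_POST_WINDOW] = True
    return mask


@dataclass(frozen=True)
class SessionTrace:
    """Arrays extracted once per session for fast likelihood replay."""

    chosen: np.ndarray  # 0-based stimulus index of the chosen option
    unchosen: np.ndarray
    rewards: np.ndarray  # drops delivered
    post: np.ndarray  # post-reversal period mask

    @classmethod
    def from_session(cls, session: Session) -> "SessionTrace":
        chosen = np.array([stim_index(t.choice) for t in session.trials], dtype=np.int64)
        unchosen = np.array([stim_index(t.unchosen) for t in session.trials], dtype=np.int64)
        rewards = np.array([t.reward_obtained for t in session.trials], dtype=np.float64)
        return cls(chosen=chosen, unchosen=unchosen, rewards=rewards,
                   post=post_reversal_mask(session))

    @property
    def n_trials(self) -> int:
        return int(self.chosen.shape[0])


def _unpack(variant: str, params: Sequence[float]) -> tuple[float, float, float]:
    """-> (alpha_other, alpha_post, beta)."""
    if variant == "basic":
        alpha, beta = params
        return float(alpha), float(alpha), float(beta)
    if variant == "modified":
        alpha_post, alpha_other, beta = params
        return float(alpha_other), float(alpha_post), float(beta)
    raise ValidationError(f"unknown variant {variant!r}")


def negloglik(
    model: str,
    variant: str,
    params: Sequence[float],
    session: Session | SessionTrace,
) -> float:
    """Total -ln likelihood of a session's observed choices.

    ``params`` is ``(alpha, beta)`` for the basic variant and
    ``(alpha_post, alpha_other, beta)`` for the modified one. The choice
    probability at each trial is evaluated on the state before that trial's
    update; the state then evolves with the reward actually delivered.
    """
    trace = session if isinstance(session, SessionTrace) else SessionTrace.from_session(session)
    alpha_other, alpha_post, beta = _unpack(variant, params)
    kernel = exp_nll_kernel if model.upper() == "EXP" else inf_nll_kernel
    nll, bad = kernel(trace.chosen, trace.unchosen, trace.rewards, trace.post,
                      alpha_other, alpha_post, beta)
    if bad >= 0:
        raise FittingError(f"non-finite likelihood at trial {bad + 1} "
                           f"({model} {variant}, params={tuple(params)})")
    return float(nll)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_mle`."""

    alpha_bounds: tuple[float, float] = (0.0, 1.0)
    beta_bounds: tuple[float, float] = (0.0, 10.0)
    n_starts: int = 10
    seed: int = 0

    def bounds(self, variant: str) -> list[tuple[float, float]]:
        if variant == "basic":
            return [self.alpha_bounds, self.beta_bounds]
        return [self.alpha_bounds, self.alpha_bounds, self.beta_bounds]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one session x model x variant fit."""

    model: str
    variant: str
    session_id: str
    params: dict[str, float]
    loglik: float
    n_trials: int
    n_starts: int
    n_converged: int
    flat_likelihood: bool  # beta-hat ~ 0: alpha unidentifiable

    @property
    def k(self) -> int:
        """Number of free parameters (2 basic, 3 modified)."""
        return len(self.params)

    @property
    def alpha_reported(self) -> float:
        """The learning rate carried into summaries (post-reversal one if present)."""
        return self.params.get("alpha_post", self.params.get("alpha", np.nan))


_PARAM_NAMES = {"basic": ("alpha", "beta"),
                "modified": ("alpha_post", "alpha_other", "beta")}


def fit_mle(
    model: str,
    variant: str,
    session: Session,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Multi-start bounded MLE of one model variant on one session."""
    model = model.upper()
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    trace = SessionTrace.from_session(session)
    if variant == "modified" and not trace.post.any():
        raise FittingError(
            f"session {session.session_id}: modified variant needs >= 1 post-reversal trial"
        )
    bounds = config.bounds(variant)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=config.seed)
    starts = qmc.scale(sampler.random(config.n_starts), lo, hi)

    def objective(x: np.ndarray) -> float:
        return negloglik(model, variant, x, trace)

    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or n_converged == 0:
        raise FittingError(
            f"session {session.session_id}: no start converged "
            f"({model} {variant}, {config.n_starts} starts)"
        )
    names = _PARAM_NAMES[variant]
    params = {name: float(v) for name, v in zip(names, best.x)}
    return FitResult(
        model=model,
        variant=variant,
        session_id=session.session_id,
        params=params,
        loglik=-float(best.fun),
        n_trials=trace.n_trials,
        n_starts=config.n_starts,
        n_converged=n_converged,
        flat_likelihood=bool(params["beta"] < 1e-6),
    )


def fit_sessions(
    sessions: Sequence[Session],
    models: Sequence[str] = MODELS,
    variants: Sequence[str] = VARIANTS,
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit every session x model x variant; one tidy row per fit."""
    rows = []
    for s in sessions:
        for m in models:
            for v in variants:
                fit = fit_mle(m, v, s, config)
                row = {
                    "session_id": s.session_id,
                    "subject": s.subject,
                    "task": s.task,
                    "treatment": s.treatment,
                    "model": fit.model,
                    "variant": fit.variant,
                    "loglik": fit.loglik,
                    "n_trials": fit.n_trials,
                    "k": fit.k,
                    "n_converged": fit.n_converged,
                    "flat_likelihood": fit.flat_likelihood,
                    "alpha": np.nan,
                    "alpha_post": np.nan,
                    "alpha_other": np.nan,
                    "beta": np.nan,
                }
                row.update(fit.params)
                rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "MODELS", "VARIANTS",
    "post_reversal_mask", "SessionTrace", "negloglik",
    "FitConfig", "FitResult", "fit_mle", "fit_sessions",
]
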