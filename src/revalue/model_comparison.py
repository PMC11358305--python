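"""BIC-based Bayesian comparison of the EXP and INF models.

For each session, BIC = k*ln(n) - 2*lnL (k free parameters, n completed
trials), and the posterior probability of model m under a uniform prior is
proportional to exp(-BIC_m / 2), normalized over the compared models. The
EXP-vs-INF question is asked of the basic variants by default; session-level
posteriors are then averaged per task/arm. A summed-BIC mode (posterior of
the total evidence across sessions) is also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ValidationError


def bic(logL: float, k: int, n: int) -> float:
    """Bayesian information criterion: k*ln(n) - 2*logL."""
    if n < 1:
        raise ValidationError(f"n={n} must be >= 1")
    if k < 0:
        raise ValidationError(f"k={k} must be >= 0")
    return k * math.log(n) - 2.0 * logL


@dataclass(frozen=True)
class ModelPosterior:
    session_id: str
    models: tuple[str, ...]
    bics: tuple[float, ...]
    posteriors: tuple[float, ...]

    def posterior(self, model: str) -> float:
        return self.posteriors[self.models.index(model)]


def model_posteriors(
    bics: dict[str, float],
    priors: dict[str, float] | None = None,
    session_id: str = "",
) -> ModelPosterior:
    """Posterior model probabilities from per-model BICs.

    posterior_m  propto  prior_m * exp(-BIC_m / 2), normalized; computed with
    a max-shift so arbitrarily large BICs stay finite.
    """
    if len(bics) < 2:
        raise ValidationError("need >= 2 models to compare")
    models = tuple(bics)
    b = np.array([bics[m] for m in models], dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValidationError(f"non-finite BIC in {bics}")
    if priors is None:
        pr = np.full(len(models), 1.0 / len(models))
    else:
        pr = np.array([priors[m] for m in models], dtype=float)
        pr = pr / pr.sum()
    log_ev = -0.5 * b
    log_ev -= log_ev.max()
    w = pr * np.exp(log_ev)
    w /= w.sum()
    return ModelPosterior(session_id=session_id, models=models,
                          bics=tuple(b), posteriors=tuple(w))


def compare_sessions(
    fits: pd.DataFrame,
    variant: str = "basic",
    priors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-session EXP-vs-INF posteriors from a tidy fit table.

    ``fits`` is the output of :func:`revalue.fitting.fit_sessions`; rows of
    the requested variant are used. Returns one row per session with BICs
    and posteriors for both models.
    """
    sub = fits[fits["variant"] == variant]
    rows = []
    for sid, grp in sub.groupby("session_id", sort=False):
        bics = {
            r.model: bic(r.loglik, int(r.k), int(r.n_trials))
            for r in grp.itertuples(index=False)
        }
        post = model_posteriors(bics, priors=priors, session_id=str(sid))
        meta = grp.iloc[0]
        row = {"session_id": sid, "subject": meta.subject, "task": meta.task,
               "treatment": meta.treatment}
        for m in post.models:
            row[f"bic_{m}"] = post.bics[post.models.index(m)]
            row[f"posterior_{m}"] = post.posterior(m)
        rows.append(row)
    return pd.DataFrame(rows)


def summed_bic_posteriors(
    fits: pd.DataFrame,
    variant: str = "basic",
    priors: dict[str, float] | None = None,
) -> ModelPosterior:
    """Posterior from BICs summed across all sessions (pooled evidence)."""
    sub = fits[fits["variant"] == variant]
    totals: dict[str, float] = {}
    for model, grp in sub.groupby("model", sort=False):
        totals[str(model)] = float(
            sum(bic(r.loglik, int(r.k), int(r.n_trials)) for r in grp.itertuples(index=False))
        )
    return model_posteriors(totals, priors=priors, session_id="<summed>")


__all__ = ["bic", "ModelPosterior", "model_posteriors", "compare_sessions",
           "summed_bic_posteriors"]
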