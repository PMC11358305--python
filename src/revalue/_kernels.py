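"""Compiled inner loops for sequential likelihood replay.

Both kernels walk a session once, accumulating -ln p(observed choice) from
the state *before* each trial's update, then updating the state with the
delivered reward. ``alpha_post`` applies where ``post_mask`` is set,
``alpha_other`` elsewhere (pass equal values for the basic model variants).

They return ``(nll, bad_trial)`` where ``bad_trial`` is the 0-based index of
the first non-finite intermediate, or -1 on success. The pure-Python
per-trial functions in :mod:`revalue.agents` are the reference
implementation these kernels are tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def _log_sigmoid(d):
    # log(1 / (1 + exp(-d))), overflow-safe
    if d >= 0.0:
        return -np.log1p(np.exp(-d))
    return d - np.log1p(np.exp(d))


@njit(cache=True)
def exp_nll_kernel(c_idx, u_idx, rewards, post_mask, alpha_other, alpha_post, beta):
    v = np.zeros(5)
    nll = 0.0
    for t in range(c_idx.shape[0]):
        i = c_idx[t]
        j = u_idx[t]
        logp = _log_sigmoid(beta * (v[i] - v[j]))
        if not np.isfinite(logp):
            return np.nan, t
        nll -= logp
        a = alpha_post if post_mask[t] else alpha_other
        v[i] -= a * (v[i] - rewards[t])
    return nll, -1


@njit(cache=True)
def inf_nll_kernel(c_idx, u_idx, rewards, post_mask, alpha_other, alpha_post, beta):
    # fixed value tables: pattern A gives stimulus k -> k+1 drops (0-based k),
    # pattern B gives 5-k; their softmax logit difference is +/- beta*(i-j)
    w = 0.5
    nll = 0.0
    for t in range(c_idx.shape[0]):
        i = c_idx[t]
        j = u_idx[t]
        d = beta * (i - j)
        if d >= 0.0:
            e = np.exp(-d)
            p_a = 1.0 / (1.0 + e)
            p_b = e / (1.0 + e)
        else:
            e = np.exp(d)
            p_a = e / (1.0 + e)
            p_b = 1.0 / (1.0 + e)
        p = w * p_a + (1.0 - w) * p_b
        if p < _TINY:
            p = _TINY
        if not np.isfinite(p):
            return np.nan, t
        nll -= np.log(p)
        a = alpha_post if post_mask[t] else alpha_other
        va = float(i + 1)
        vb = float(5 - i)
        expected = w * va + (1.0 - w) * vb
        w = w - a * (expected - rewards[t]) * (va - vb)
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
    return nll, -1
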