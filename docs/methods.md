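# Methods notes

## Models

Both choice models operate on five stimuli S1–S5 worth 1–5 drops of juice
under one of two mirror-image association patterns (A: S_i → i drops,
B: S_i → 6 − i).

**EXP** is a standard Rescorla–Wagner delta-rule learner: subjective values
V (one per stimulus, drops units, all zero at session start), two-option
softmax choice with inverse temperature β, and an update of the chosen
stimulus only, V_i ← V_i − α(V_i − r_obs). It carries no knowledge of the
pattern structure; reversals must be relearned from outcomes.

**INF** assumes the two patterns are known and tracks a single confidence
weight w (0.5 at session start) that pattern A is in force. Choice is the
w-mixture of the softmax over the pattern-A value table and the softmax over
the pattern-B table; w follows stochastic gradient descent on the squared
reward-prediction error and is hard-clipped to [0, 1]. One surprising
outcome can flip w and thereby update the value of every pair at once, which
is what produces correct "inference" choices on pairs not seen since the
reversal.

The fitted softmax is the symmetric two-option form
exp(βV_i)/(exp(βV_i)+exp(βV_j)) for both models; it has the correct uniform
limit at β = 0 and matches the mixture components of the INF model.

Both models come in a *basic* variant (α, β) and a *modified* variant with
separate learning rates for the post-reversal period (α_post) and all other
trials (α_other). The post-reversal period is all trials from the reversal
onward in NOVEL sessions and the five trials starting at each reversal in
FAMILIAR sessions (truncated at session end). α_post is the learning rate
reported in summaries; it isolates updating where the contingencies have
just changed.

## Task engine

- Pair schedule: each 10-trial block is an independent uniform permutation of
  all 10 unordered pairs; left/right placement is a fair coin per trial.
  Side plays no role in any analysis.
- NOVEL: 90 acquisition trials under pattern A, reversal regardless of
  behavior, 210 post-reversal trials under pattern B. A "new stimulus set
  per session" is equivalent, for these models, to resetting agent state at
  session start, so stimulus ids are always S1–S5.
- FAMILIAR: the criterion "optimal-choice rate over 30 consecutive trials
  above 76%" is evaluated on a sliding window after every completed trial
  and implemented as ≥ 23/30 correct — the smallest count strictly exceeding
  the threshold (23/30 ≈ 76.7%). The window resets at each reversal, so no
  window spans a boundary and consecutive reversals are at least 30 trials
  apart. The initial pattern is a seeded coin flip unless pinned in the
  task spec. Default session lengths are 300 trials (400 for the second
  synthetic subject, mirroring the two-animal design).
- The agent contract is `choose(pair, rng) → stimulus`,
  `observe(chosen, reward, post_reversal=...)`; an agent returning an
  un-offered stimulus raises a contract error. Each session runner spawns
  separate child RNG streams for the task schedule and the agent's choices
  from the caller's generator, so a session is a pure function of one seed.

## Fitting

- Per-session maximum likelihood only; no pooling across sessions.
- Likelihood replay: the probability of the observed choice at trial t uses
  the state before trial t's update; the state then evolves with the reward
  actually delivered (not the model's expectation).
- Bounds α ∈ [0, 1] (the INF gradient is scaled by (V^A−V^B) ∈ [−4, 4], so
  α > 1 is wildly unstable), β ∈ [0, 10]; both config-overridable.
- Multi-start: 10 starting points from a seeded Latin hypercube over the
  bounds, each refined with L-BFGS-B; the best converged start wins; a
  fitting error is raised only if no start converges. The grid-oracle test
  checks the result against a dense 200×200 lattice.
- Degenerate fits: at β̂ ≈ 0 the likelihood is flat in α; such fits are
  returned with a `flat_likelihood` diagnostic flag rather than
  re-parameterized.
- The sequential likelihood loops are numba-compiled kernels; the public
  per-trial functions in `agents` are pure Python and serve as the reference
  implementation the kernels are tested against (equality to 1e-10 on random
  fixtures). Kernels use stable log-sigmoid forms and floor the mixture
  probability at 1e-300 before taking logs.

## Model comparison

BIC = k·ln n − 2·lnL with k = 2 (basic) or 3 (modified) and n = completed
trials in the session; posteriors ∝ exp(−BIC/2) under a uniform prior
(priors exposed), computed with a max-shift. The EXP-vs-INF question is
asked of the basic variants, per session, and session posteriors are then
averaged per arm; a pooled summed-BIC mode is also provided since either
aggregation is defensible.

## Behavioral metrics

- Optimal choice: the offered stimulus with the larger in-force reward.
- Phase windows: NOVEL Pre/PoE/PoL = 90 trials before the reversal, first
  100 after, next 110 (partitioning the 300 trials); FAMILIAR = 10 before /
  first 5 / next 5 around each reversal, per-reversal means averaged across
  reversals (not pooled trials). FAMILIAR Pre windows are truncated, with a
  logged warning, where they would overlap the previous reversal's
  post-reversal trials.
- Experience events: within the PoE window, an unpredicted positive
  (negative) experience is the first choice of a 4–5-drop (1–2-drop) option
  after an earlier presentation where it was offered and not chosen; the
  evaluation trial is the next PoE trial offering that option. One event per
  option per session. The "preceding trial" is the most recent presentation
  of that option, not the immediately preceding trial overall. By default
  the non-choice and the choice must both lie in PoE (`scope="poe"`); a
  `scope="post"` mode relaxes the search to the whole post-reversal period
  because the definition is ambiguous on that point; evaluation trials
  always lie in PoE.
- Inference trials: per FAMILIAR reversal, the earliest trial after the
  first post-reversal trial whose offered pair shares no stimulus with that
  first trial's pair, searched up to the next reversal (no further cap).
- 10-trial block averages drop a trailing partial block (standard sessions
  are multiples of 10).
- Proportion shifted = ((F1N − F1D) + (F2N − F2D)) / (F1N + F2N), with a
  validation error on a zero baseline.

## Synthetic cohorts

The generator emulates the *layout and generative logic* of the silencing
experiments: 2 subjects × {vehicle, DCZ} × N sessions (7 NOVEL / 6 FAMILIAR
for whole-region presets, 5 for the pathway presets), EXP agents on NOVEL
and INF agents on FAMILIAR, and silencing modeled solely as a
multiplicative reduction (default 0.5) of α_post in the treated arm, with β
untouched. Default generating parameters — EXP α = 0.15, β = 1.5; INF
α = 0.05, β = 1.5 — are package constants chosen so that simulated learning
curves have the right qualitative shape (acquisition within ~90 NOVEL
trials; FAMILIAR recovery above 0.8 optimal within about five post-reversal
trials; criterion-triggered reversals roughly every 30–40 trials). They are
not fitted to any animal.

What the generator deliberately does not reproduce: aborted/repeated
trials, reaction times, motivation or satiety drift, attention lapses,
session exclusions, or any mixture/arbitration between the two strategies
within one agent. Because cohorts are generated by the same model families
that are fitted, the recovery and model-selection results demonstrate
internal consistency of the estimation chain (no misspecification), not
validity on real behavior.

Ground truth is emitted as a separate table and is never read by the
fitting stage. Cohorts, fits and pipeline reports are pure functions of
their seeds; the pipeline report hash excludes the output directory so the
same analysis hashes identically wherever it is written.

## Statistics in the pipeline report

Arm contrasts use means ± s.e.m. and independent-label permutation tests
(2000 resamples by default): one-sided (treated < control) for α_post,
where the simulated effect can only lower it, and two-sided for β, where
any signal would be spurious. ANOVA-style inference is intentionally not
reproduced.

## Problem sizes

Test and acceptance runs use 20 sessions per recovery study, 40 per
model-selection study, 10 master seeds per silencing preset and 100
sessions for the brute-force criterion recheck — large enough for stable
medians and binomial allowances at the 5% level while keeping the whole
suite in the tens of seconds on one core.

## Known limitations

- α_post in the FAMILIAR/INF modified fit rests on only ~5 trials per
  reversal (~30–50 trials per session), so its per-session estimates are
  noisy; contrasts are assessed across sessions.
- The INF model's α_other is weakly identified when w saturates at 0/1
  between reversals (updates clip, leaving the likelihood flat in α).
- No exclusion logic for sessions or trials is implemented; logs are
  assumed to contain completed trials only.
- The devaluation statistic is implemented as a pure function of choice
  counts; the behavioral protocol that produces those counts is not
  simulated.
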