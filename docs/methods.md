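# Methods

## The task

An agent plays 250 independent trials of an advisor/card game. Each trial
has three timesteps: the trial begins (t1), advice arrives (t2), and the
agent chooses a card and receives feedback (t3). A correct card (blue or
green) is drawn uniformly each trial. An advisor recommends a card; the
advisor's *scheduled* intention follows one of two schedules — trustworthy
on every trial, or 125 untrustworthy trials followed by 125 trustworthy
ones (optionally rotated so that the initial untrustworthy block has a
chosen length, with the removed trials appended at the end) — and the
intention *realized* on a trial flips away from the schedule with
probability 0.1. A trustworthy advisor names the correct card; an
untrustworthy one names the other card. Feedback is a truthful readout of
whether the chosen card was correct; the agent merely *believes* it to be
imperfectly reliable. In models with affect, the agent's trust/distrust
stance drives a hidden affective state (calm twice as likely as angry under
trust, and conversely) which is read out as a low/high arousal outcome.

Because each trial begins anew, there is no hierarchical inference across
trials. Everything the agent carries between trials is: its Dirichlet habit
counts over policies, its policy-precision state, and (in affect models)
the world's slow affective state.

## The agent

The agent is a discrete active-inference agent over a three-timestep
partially observable Markov decision process with five hidden-state factors
(advisor intention, correct card, decision, affect, trial stage) and up to
four outcome modalities (advice, feedback, arousal, observed own choice).
Four policies span each trial: {trust, distrust} × {choose blue, choose
green}; trusting/distrusting is a mental action that, in the agent's model,
*makes* the advisor trustworthy/untrustworthy at future timesteps and tilts
the affective transition.

Per timestep the agent:

1. observes the available outcomes (unavailable modalities emit explicit
   null outcomes; arousal is read once per trial, at t1);
2. infers policy-conditioned posteriors over all factors at all timesteps
   by coordinate-ascent (marginal message passing) on the variational free
   energy F, iterated to a fixed point (cap 16 sweeps, tolerance 1/128
   nats; the per-policy graphs here are nearly tree-structured, so the
   mean-field solution coincides with exact enumeration to < 1e-3 total
   variation — this is property-tested against a brute-force oracle);
3. scores each policy's expected free energy G over the remaining
   unobserved outcomes as risk plus ambiguity per modality, i.e. negative
   expected information gain minus expected log-preference. Preferences:
   +3/−3 log units for correct/incorrect feedback, [c, −c] over low/high
   arousal (the mood parameter), zero elsewhere;
4. solves the joint fixed point of the habit-weighted policy prior
   π₀ = σ(ln E − γG), posterior π = σ(ln E − F − γG), and precision
   posterior β̂ = β + (π − π₀)·G with γ = 1/β̂ (damped iteration, anchored
   at the fixed prior rate β);
5. acts where an action is due: the trust stance is enacted at t1 and the
   card at t2, each sampled from softmax(α · ln p(u)) over the marginal
   action probabilities. α only shapes behaviour — inference is invariant
   to it under action replay, which is tested.

After the final timestep the habit counts accumulate the final policy
posterior (one count per trial, split proportionally when the policy is
uncertain).

## Parameters

| parameter | symbol | default | sweep range | meaning |
|---|---|---|---|---|
| likelihood precision | a | 0.9 | 0.60–0.99 | believed feedback reliability |
| habit resistance | e0 | 2 | 2–600 | initial Dirichlet count per policy |
| mood | c | 0 | −4.5–4.5 | log-preference for low arousal |
| choice precision | α | 1.5 | 0.5–2.75 | action softmax inverse temperature |
| policy precision prior | 1/β | 1.0 | 0.25–1.75 | prior confidence in policies |
| initial consistency | — | 125 | 1–125 | initial untrustworthy block length |

Sweeps draw each parameter independently and uniformly from its range
(mood only in affect models, initial consistency only for the changing
schedule), 972 agents per set by default.

## Design choices in the underdetermined parts

Several dynamical details are not pinned down by the model equations as stated;
the choices below were fixed by requiring consistency with the reference
behaviour of the named single-agent configurations, and then frozen.

* **Feedback generation.** The environment's feedback is deterministically
  truthful. A noisy (90%-reliable) feedback process is incompatible with
  the precise-agent configurations making zero false inferences and with
  only ~42% of swept agents ever making one: misleading feedback would
  force wrong-side posteriors on ~10% of all trials for every agent. The
  "90%" reliability lives in the agent's default model (a = 0.9) and in
  the advice itself, which is wrong on 10% of trials via the intention
  flips. `emit_feedback` retains a reliability argument for counterfactual
  experiments.
* **Final-timestep policy posterior.** At t3 no outcomes remain
  unobserved, so no fresh G is computable; the start-of-trial G (computed
  before any evidence, when the card is still unknown) persists as each
  policy's appeal. This term is neutral between policies in no-affect
  models (so evidence and habits alone decide the recorded posterior) but
  mood-sensitive in affect models, which is the route by which policy
  precision and mood reach state inference through the Bayesian model
  average.
* **Precision anchoring.** β̂ is recomputed each timestep from the fixed
  prior β rather than compounded across trials. Compounding makes β
  excursion over two orders of magnitude within a run and locks habits in
  early; anchored updates keep γ fluctuating gently around 1/β, drifting
  only through the evolving (π − π₀)·G alignment. The simulated
  antipsychotic treatment permanently rescales the prior:
  1/β ← (1/β − 0.25) × 0.5 + 0.25, once, after the agent's 10th false
  posterior inference about the realized trustworthiness.
* **Affect timing.** The stance adopted on a trial updates the world's
  affect state once (per the 2/3–1/3 transition); that state is felt as
  the arousal reading at the start of the *next* trial. Within-trial
  stance-coupled arousal evidence was rejected: it hands the enacted
  stance a ×2–×4 self-confirming likelihood channel that overwhelms even
  precise feedback, contrary to the reference behaviour of the precise
  affect agents. Accordingly each policy anticipates exactly one arousal
  consequence in G.
* **Numerical floors.** All logarithms use max(p, 1e-16); β̂ is floored at
  0.05. Ties in action sampling are resolved by exact
  probability-proportional sampling.
* **Randomness.** One seeded generator per agent run; environment and
  agent draws interleave deterministically, so (configuration, schedule,
  seed) reproduces a run bit-for-bit. Sweep agents derive their seeds from
  a master seed, and the treatment flag does not consume draws, so treated
  and untreated sweeps are agent-by-agent matched.

## Scoring

A *false inference* is a trial whose final posterior puts strictly more
than 50% on the wrong realized trustworthiness state. The delusion score
(0–3) sums falsity (proportion of false-inference trials), certainty (mean
posterior confidence of the false inferences), and incorrigibility
(proportion of false inferences followed by another; a flagged final trial
is excluded from the denominator). Delusion "proper" requires, at the main
66% threshold (60%/70% sensitivity variants): falsity > 66% (halved to 33%
for the changing schedule), > 66% of false inferences held above 80%
confidence, and incorrigibility > 66%. Habit-level delusion-like priors
are flagged when the final normalized counts put > 75% on one card or one
trust state, or > 50% on distrust under the consistently trustworthy
schedule. State-space trajectories (γ, habit strength |ln e_trust/e_distrust|,
cumulative posterior change) are averaged within deciles of agents ranked
by falsity.

## What the simulations do and do not show

The task environment *is* the study's data-generating process; there is no
external data. Passing tests therefore show that the implementation
reproduces the model's internal dynamics and summary statistics under the
stated conditions — not that the model describes human behaviour. The
advisor never reacts to the agent; mood is fixed per agent; there is no
across-trial state inference; likelihood and transition arrays are not
learned.

## Problem sizes and runtime

Unit and property tests run on short runs (20–40 trials) and tiny sweeps.
The reproduction suite uses 200-agent sweeps and ~20-seed single-agent
averages; `scripts/acceptance.py` uses 648-agent sweeps by default
(`--n-agents` selects other sizes; counts are reported on the reference
972-agent basis) and completes in roughly ten minutes on one CPU. Per-agent
inference is memoized over the (at most a few dozen) distinct observation
patterns a trial can produce, which makes a 250-trial run take well under a
second.

## Known limitations

* The habit-forming precise agent averages ~83% correct card choices where
  the reference figure is 72%: the α-sharpened softmax over an
  advice-following policy posterior saturates near a 0.92 follow rate, and
  nothing in the stated equations softens it.
* Mood's influence on expected free energy is linear in c (the preference
  vector is [c, −c] by construction), so extreme-mood agents can be pushed
  into certain false inference without habits; the reference correlation
  structure implies an additional saturation of mood's influence that the
  source equations do not specify. With-affect delusion frequencies here
  run ~2–3× the reference ones, and the habit-resistance and
  policy-precision correlations with delusion score are correspondingly
  diluted.
* Dirichlet habit odds self-saturate near the feedback evidence odds
  a/(1−a), so the no-affect changing-trustworthiness set produces almost
  no graded delusion scores, where the reference set-3 correlations imply
  many.
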