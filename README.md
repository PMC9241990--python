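# advisortask

Active-inference simulations of delusion-like belief on a probabilistic
advisor/card task.

## The problem

Delusions are beliefs that are false, held with certainty, and resistant to
contradictory evidence — properties that look paradoxical for a brain doing
approximately Bayesian inference. This package implements a Bayes-optimal
active-inference agent for a simple social-inference task and shows how
moderate changes in its parameters push it into self-reinforcing false
belief. On each of 250 trials an advisor (trustworthy or not) recommends a
card; the agent decides whether to trust the advice, picks a card, and gets
feedback. The agent must infer the advisor's trustworthiness from advice,
feedback, its own choices, and (in some models) its own arousal.

It is intended for computational-psychiatry researchers and students who
want a self-contained, inspectable implementation of habit learning and
precision dynamics in a discrete active-inference agent, and of the
delusion metrics built on top of it.

## The model

The agent is a three-timestep POMDP with hidden-state factors for advisor
intention, correct card, decision, affect and trial stage. Beliefs about
states are optimized per policy by minimizing variational free energy

    F(π) = D_KL[ Q(s̃|π) ‖ P(s̃, π|õ) ] − ln P(õ)

and policies π ∈ {trust, distrust} × {blue, green} are scored by expected
free energy over unobserved outcomes,

    G(π) = −E_Q[ D_KL[ Q(s̃|õ,π) ‖ Q(s̃|π) ] ] − E_Q[ ln P(õ|c) ]

(risk plus ambiguity: information gain and preferences, with c giving +3/−3
log-preference for correct/incorrect feedback and [c, −c] over arousal —
the mood parameter). Policy selection combines Dirichlet habits E = e/Σe,
evidence and a precision γ:

    π₀ = σ(ln E − γ·G),   π = σ(ln E − F − γ·G),
    β̂ = β + (π − π₀)·G,   γ = 1/β̂

solved as a joint fixed point, so precision deflates when evidence
contradicts the appealing policies and inflates when it confirms them.
Habits accumulate the final policy posterior each trial (e ← e + π_T).
Crucially, trusting/distrusting is a *mental* action: in the agent's model
it determines the advisor's state, so the most probable policies dominate
state inference through the Bayesian model average Q(s) = Σ_π Q(s|π)Q(π).
That loop — habits → policies → beliefs → habits, amplified by γ — is the
attractor that traps beliefs.

Runs are scored for false inferences (final posterior on the wrong side of
0.5 about the realized trustworthiness), a 0–3 delusion score (falsity +
certainty + incorrigibility), and threshold-based delusion classification;
972-agent parameter sweeps reproduce the population analyses, including a
simulated antipsychotic that halves the policy-precision prior toward the
population minimum after an agent's 10th false inference.

## Worked example

A habit-forming agent with reduced likelihood precision (a = 0.75) and
mildly negative mood, facing an advisor who is untrustworthy for 125 trials
and then trustworthy:

```
$ advisortask run-agent --a 0.75 --e0 2 --mood -1 --affect --inv-beta 1.0 \
      --alpha 1.5 --seed 3 --sequence changing_trustworthiness --out-dir demo
proportion correct: 0.520
false inferences: 117 (46.8%)
delusion score: 2.160 (delusional at 66%: True)
records written to demo/trials.csv
```

The agent acquires a distrust habit during the first half and then keeps
inferring "untrustworthy" — with high confidence, trial after trial —
through 125 trials of mostly honest advice: 46.8% of its 250 posterior
inferences are false, and it meets all three delusion criteria (falsity,
certainty, incorrigibility). The same agent with precise likelihood
(a = 0.9) and neutral mood instead profits from its habit:

```
$ advisortask run-agent --a 0.9 --e0 2 --seed 3 --out-dir demo2
proportion correct: 0.868
false inferences: 13 (5.2%)
delusion score: 0.784 (delusional at 66%: False)
```

`advisortask run-sweep --set 4 --n-agents 972 --seed 0 --out-dir sweep4`
runs a full population sweep (the five canonical sets cover
consistent/changing advisors × affect on/off × treatment) and writes
per-agent and summary tables, Spearman correlations of every parameter with
delusion score, a standardized interaction regression, and decile
state-space trajectories.

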