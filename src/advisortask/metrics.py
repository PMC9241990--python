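"""Scoring of agent runs: false inferences, delusion score and criteria.

A *false inference* is a trial on which the agent's final posterior assigns
more than 50% to the wrong realized trustworthiness state.  The *delusion
score* (0 to 3) sums three components over a run:

* falsity -- the proportion of trials with a false inference;
* certainty -- the mean confidence (posterior probability of the believed,
  false state) across false inferences;
* incorrigibility -- the proportion of false inferences followed by another
  false inference on the next trial.

Delusion "proper" requires all three to exceed a threshold (66% in the main
analysis, with 60%/70% sensitivity variants): falsity above the threshold
(halved in changing-trustworthiness runs, where a fixed belief can be wrong
on at most half the trials), more than the threshold proportion of false
inferences held at >80% confidence, and incorrigibility above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_environment import TRUSTWORTHY

CONFIDENCE_CUTOFF = 0.8       # a false inference "held with certainty"
THRESHOLDS = (60, 66, 70)     # percent; 66 is the main analysis
HABIT_DOMINANCE = 0.75        # habit marginal counting as delusion-like
DISTRUST_DOMINANCE = 0.5      # distrust marginal vs a trustworthy advisor


@dataclass
class DelusionAssessment:
    false_flags: np.ndarray
    falsity: float
    certainty_mean: float
    certainty_high_share: float   # share of false inferences above the cutoff
    incorrigibility: float
    delusion_score: float
    is_delusion: dict             # threshold percent -> bool
    habit_strength: float
    card_habit_delusion: bool
    advisor_habit_delusion: bool


def flag_false_inferences(posterior_trust: np.ndarray,
                          true_intention: np.ndarray) -> np.ndarray:
    """True where the posterior puts >50% (strictly) on the wrong realized
    trustworthiness state; exact ties are not flagged."""
    posterior_trust = np.asarray(posterior_trust, dtype=float)
    p_true = np.where(np.asarray(true_intention) == TRUSTWORTHY,
                      posterior_trust, 1.0 - posterior_trust)
    return p_true < 0.5


def delusion_score(posterior_trust: np.ndarray, true_intention: np.ndarray,
                   false_flags: np.ndarray | None = None):
    """The three components and their sum.

    Returns ``(falsity, certainty_mean, certainty_high_share,
    incorrigibility, score)``.  The certainty of a false inference is the
    posterior probability of the believed (false) state.  A false inference
    on the final trial has no successor and is excluded from the
    incorrigibility denominator.
    """
    posterior_trust = np.asarray(posterior_trust, dtype=float)
    n = len(posterior_trust)
    if n == 0:
        raise ValueError("need at least one trial")
    if false_flags is None:
        false_flags = flag_false_inferences(posterior_trust, true_intention)
    flags = np.asarray(false_flags, dtype=bool)

    falsity = flags.mean()
    if flags.any():
        p_true = np.where(np.asarray(true_intention) == TRUSTWORTHY,
                          posterior_trust, 1.0 - posterior_trust)
        conf = 1.0 - p_true[flags]
        certainty_mean = float(conf.mean())
        certainty_high_share = float((conf > CONFIDENCE_CUTOFF).mean())
    else:
        certainty_mean = 0.0
        certainty_high_share = 0.0

    idx = np.flatnonzero(flags)
    idx = idx[idx < n - 1]  # a flagged final trial has no successor
    if len(idx):
        incorrigibility = float(flags[idx + 1].mean())
    else:
        incorrigibility = 0.0

    score = float(falsity) + certainty_mean + incorrigibility
    return float(falsity), certainty_mean, certainty_high_share, \
        incorrigibility, score


def classify_delusion(falsity: float, certainty_high_share: float,
                      incorrigibility: float, sequence_kind: str,
                      threshold: int = 66) -> bool:
    """All three criteria strictly exceeded at the given percent threshold.

    The falsity threshold is halved for changing-trustworthiness runs.
    """
    if threshold not in THRESHOLDS:
        raise ValueError(f"threshold must be one of {THRESHOLDS}")
    t = threshold / 100.0
    falsity_t = t / 2.0 if sequence_kind == "changing_trustworthiness" else t
    return bool(falsity > falsity_t and certainty_high_share > t
                and incorrigibility > t)


def habit_strength(e: np.ndarray) -> float:
    """``|ln(e_trust / e_distrust)|`` over the summed trust/distrust counts.

    Policies are ordered (trust-blue, trust-green, distrust-blue,
    distrust-green).
    """
    e = np.asarray(e, dtype=float)
    return float(abs(np.log(e[:2].sum() / e[2:].sum())))


def classify_habit_delusion(e_final: np.ndarray,
                            sequence_kind: str) -> tuple[bool, bool]:
    """Delusion-like priors over policies from the final Dirichlet counts.

    A card habit: >75% of normalized mass on one card.  An advisor habit:
    >75% on one trust state, or >50% on distrusting a consistently
    trustworthy advisor.
    """
    e = np.asarray(e_final, dtype=float)
    E = e / e.sum()
    p_blue = E[0] + E[2]
    p_trust = E[0] + E[1]
    card_flag = max(p_blue, 1 - p_blue) > HABIT_DOMINANCE
    advisor_flag = max(p_trust, 1 - p_trust) > HABIT_DOMINANCE
    if sequence_kind == "consistently_trustworthy" \
            and (1 - p_trust) > DISTRUST_DOMINANCE:
        advisor_flag = True
    return bool(card_flag), bool(advisor_flag)


def assess_run(records, sequence_kind: str) -> DelusionAssessment:
    """Full delusion assessment of one agent's trial records."""
    post = np.array([r.posterior_trust for r in records])
    truth = np.array([r.true_intention for r in records])
    flags = flag_false_inferences(post, truth)
    falsity, cmean, chigh, incorr, score = delusion_score(post, truth, flags)
    is_del = {thr: classify_delusion(falsity, chigh, incorr, sequence_kind, thr)
              for thr in THRESHOLDS}
    e_final = records[-1].habit_counts_snapshot
    card_flag, advisor_flag = classify_habit_delusion(e_final, sequence_kind)
    return DelusionAssessment(
        false_flags=flags, falsity=falsity, certainty_mean=cmean,
        certainty_high_share=chigh, incorrigibility=incorr,
        delusion_score=score, is_delusion=is_del,
        habit_strength=habit_strength(e_final),
        card_habit_delusion=card_flag, advisor_habit_delusion=advisor_flag)


def trajectory_summary(agent_records: list) -> dict:
    """Decile-averaged per-trial trajectories of policy precision, habit
    strength and cumulative trial-to-trial posterior change.

    Agents are sorted by their proportion of false inferences and split into
    ten equal-size deciles (remainders spread over the early deciles).
    Returns arrays of shape (10, n_trials) under keys ``gamma``,
    ``habit_strength`` and ``cumulative_change``, plus each decile's mean
    false-inference proportion under ``falsity``.
    """
    n_agents = len(agent_records)
    if n_agents < 10:
        raise ValueError("need at least 10 agents for decile trajectories")
    n_trials = len(agent_records[0])

    falsities = []
    gammas = np.empty((n_agents, n_trials))
    strengths = np.empty((n_agents, n_trials))
    changes = np.empty((n_agents, n_trials))
    for i, records in enumerate(agent_records):
        post = np.array([r.posterior_trust for r in records])
        truth = np.array([r.true_intention for r in records])
        falsities.append(flag_false_inferences(post, truth).mean())
        gammas[i] = [r.gamma_T for r in records]
        strengths[i] = [habit_strength(r.habit_counts_snapshot) for r in records]
        deltas = np.abs(np.diff(post, prepend=post[0]))
        changes[i] = np.cumsum(deltas)

    return decile_trajectories(np.array(falsities), gammas, strengths, changes)


def decile_trajectories(falsities: np.ndarray, gammas: np.ndarray,
                        strengths: np.ndarray, changes: np.ndarray) -> dict:
    """Decile means of per-agent, per-trial trajectory arrays, with agents
    ordered by false-inference proportion."""
    order = np.argsort(falsities, kind="stable")
    groups = np.array_split(order, 10)
    out = {"gamma": [], "habit_strength": [], "cumulative_change": [],
           "falsity": []}
    for g in groups:
        out["gamma"].append(gammas[g].mean(axis=0))
        out["habit_strength"].append(strengths[g].mean(axis=0))
        out["cumulative_change"].append(changes[g].mean(axis=0))
        out["falsity"].append(float(falsities[g].mean()))
    return {k: np.array(v) for k, v in out.items()}
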