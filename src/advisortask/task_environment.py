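"""The advisor/card task: the true generative process behind every simulation.

An agent plays 250 trials.  On each trial there is a correct card (blue or
green, drawn uniformly) and an advisor who recommends a card.  The advisor's
*scheduled* intention (trustworthy or untrustworthy) follows one of two
schedules; the intention actually *realized* on a trial flips away from the
schedule with probability 0.1, independently per trial.  A trustworthy
advisor names the correct card, an untrustworthy one names the other card,
so advice is correct 90% of the time under a trustworthy schedule (the only
exteroceptive noise in the task).  Feedback on the agent's card choice is a
truthful readout of whether the choice matched the correct card; the agent
merely *believes* it to be imperfectly reliable (its likelihood precision
``a``, nominally 0.9).  In models with affect, the agent's trust/distrust
stance drives a hidden affective state (calm twice as likely as angry under
trust, and conversely), which is read out as a low/high arousal
interoceptive outcome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

N_TRIALS = 250

# intention codes
TRUSTWORTHY = 0
UNTRUSTWORTHY = 1

# card codes
BLUE = 0
GREEN = 1

# affect codes / arousal codes
CALM = 0
ANGRY = 1
LOW = 0
HIGH = 1

# feedback codes
CORRECT = 0
INCORRECT = 1

INTENTION_FLIP_PROB = 0.1    # per-trial flip away from the scheduled intention
NOMINAL_RELIABILITY = 0.9    # the agent's default belief in feedback reliability

#: Affective transition under the trust / distrust stance: columns are the
#: previous affect state, rows (calm, angry) the next.  Both columns are
#: equal, so the stance alone sets the odds: calm is twice as likely as angry
#: under trust, and the converse under distrust.
AFFECT_TRANSITION = {
    "trust": np.array([[2 / 3, 2 / 3], [1 / 3, 1 / 3]]),
    "distrust": np.array([[1 / 3, 1 / 3], [2 / 3, 2 / 3]]),
}

SEQUENCE_KINDS = ("consistently_trustworthy", "changing_trustworthiness")


@dataclass(frozen=True)
class TaskSequence:
    """A full schedule for one 250-trial run.

    ``scheduled_intention[t]`` is the advisor's scheduled state on trial t
    (before the 10% realization flip) and ``correct_card[t]`` the correct
    card.  ``initial_consistency`` only applies to the changing kind: the
    first block of untrustworthy trials is truncated to this length and the
    removed trials are appended at the end of the run, keeping the total
    number of scheduled untrustworthy trials at 125.
    """

    kind: str
    scheduled_intention: np.ndarray
    correct_card: np.ndarray
    initial_consistency: int
    seed: int
    n_trials: int = N_TRIALS

    def __post_init__(self):
        if self.kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if len(self.scheduled_intention) != self.n_trials:
            raise ValueError("schedule length mismatch")
        if len(self.correct_card) != self.n_trials:
            raise ValueError("card sequence length mismatch")


def make_sequence(kind: str, initial_consistency: int = 125, seed: int = 0,
                  n_trials: int = N_TRIALS) -> TaskSequence:
    """Build a task schedule.

    ``consistently_trustworthy``: trustworthy on every trial.

    ``changing_trustworthiness``: the base schedule is 125 untrustworthy then
    125 trustworthy trials.  ``initial_consistency`` (1..125) rotates the
    block structure: the last ``125 - initial_consistency`` untrustworthy
    trials are removed from the first block and appended to the end of the
    sequence, so the run is untrustworthy for ``initial_consistency`` trials,
    then trustworthy, then untrustworthy again for the remainder.

    Correct cards are independent uniform draws (a pure function of
    ``(kind, initial_consistency, seed)``).
    """
    if kind not in SEQUENCE_KINDS:
        raise ValueError(f"unknown sequence kind {kind!r}")
    half = n_trials // 2
    if kind == "changing_trustworthiness":
        if not 1 <= initial_consistency <= half:
            raise ValueError(
                f"initial_consistency must be in [1, {half}], got {initial_consistency}")
        moved = half - initial_consistency
        scheduled = np.concatenate([
            np.full(initial_consistency, UNTRUSTWORTHY),
            np.full(half, TRUSTWORTHY),
            np.full(moved, UNTRUSTWORTHY),
        ])
    else:
        scheduled = np.full(n_trials, TRUSTWORTHY)
    rng = np.random.default_rng(seed)
    cards = rng.integers(0, 2, size=n_trials)
    return TaskSequence(kind=kind, scheduled_intention=scheduled,
                        correct_card=cards, initial_consistency=initial_consistency,
                        seed=seed, n_trials=n_trials)


def realize_trial(sequence: TaskSequence, trial_index: int,
                  rng: np.random.Generator) -> tuple[int, int]:
    """Realize one trial: flip the scheduled intention with probability 0.1
    and derive the advice deterministically from the realized intention.

    Returns ``(true_intention, advice)``.
    """
    scheduled = sequence.scheduled_intention[trial_index]
    true_intention = int(scheduled)
    if rng.random() < INTENTION_FLIP_PROB:
        true_intention = 1 - true_intention
    card = int(sequence.correct_card[trial_index])
    advice = card if true_intention == TRUSTWORTHY else 1 - card
    return true_intention, advice


def emit_feedback(choice: int, correct_card: int,
                  rng: np.random.Generator | None = None,
                  reliability: float = 1.0) -> int:
    """Feedback on a card choice: a truthful readout of whether the choice
    matched the correct card.

    The task's unreliability lives in the advice (via the 10% intention
    flips), not in the feedback; the agent's belief that feedback is only
    ``a``-reliable is a property of its model.  ``reliability`` < 1 makes
    the readout itself noisy, for counterfactual experiments.
    """
    truthful = CORRECT if choice == correct_card else INCORRECT
    if reliability >= 1.0:
        return truthful
    if rng is None:
        raise ValueError("rng required when reliability < 1")
    return truthful if rng.random() < reliability else 1 - truthful


def sample_affect(trust_action: int, rng: np.random.Generator) -> int:
    """Next hidden affect state given the enacted stance (0 trust, 1 distrust).

    Both columns of the affective transition are equal, so the previous
    affect state is irrelevant: calm with probability 2/3 under trust and
    1/3 under distrust.
    """
    key = "trust" if trust_action == 0 else "distrust"
    p_calm = AFFECT_TRANSITION[key][CALM, 0]
    return CALM if rng.random() < p_calm else ANGRY


def emit_arousal(affect_state: int) -> int:
    """Deterministic interoceptive readout: calm -> low, angry -> high."""
    return LOW if affect_state == CALM else HIGH


def sequence_to_csv(sequence: TaskSequence, path) -> None:
    """Serialize a schedule for audit/replay (trial, scheduled intention, card)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "scheduled_intention", "correct_card"])
        for t in range(sequence.n_trials):
            writer.writerow([
                t,
                "trustworthy" if sequence.scheduled_intention[t] == TRUSTWORTHY else "untrustworthy",
                "blue" if sequence.correct_card[t] == BLUE else "green",
            ])


def sequence_from_csv(path, kind: str = "changing_trustworthiness",
                      initial_consistency: int = 125, seed: int = 0) -> TaskSequence:
    """Rehydrate a schedule written by :func:`sequence_to_csv`."""
    scheduled, cards = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            scheduled.append(TRUSTWORTHY if row["scheduled_intention"] == "trustworthy"
                             else UNTRUSTWORTHY)
            cards.append(BLUE if row["correct_card"] == "blue" else GREEN)
    return TaskSequence(kind=kind, scheduled_intention=np.array(scheduled),
                        correct_card=np.array(cards),
                        initial_consistency=initial_consistency, seed=seed,
                        n_trials=len(cards))
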