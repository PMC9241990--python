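"""Construction of the agent's generative model and the true task process.

The agent models one trial of the advisor/card task as a three-timestep
partially observable Markov decision process over five hidden-state factors:

* advisor intention  (trustworthy / untrustworthy)
* correct card       (blue / green)
* decision           (null / blue / green)
* affect             (calm / angry) -- only in models with affect
* trial stage        (start / advice / feedback)

and up to four outcome modalities: advice, feedback, arousal (affect models
only) and the proprioceptive readout of the agent's own choice.  Lower-case
arrays (a, b, c, d, e) belong to the agent; the environment's upper-case
counterparts differ only in the feedback reliability (fixed at 0.9 in the
world, the parameter ``a`` in the agent) and in the advisor transition, which
in the agent's model is under the control of the trust/distrust mental
action: trusting *makes* the advisor trustworthy in the agent's model of the
future, distrusting makes them untrustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_environment import AFFECT_TRANSITION, TaskSequence

LOG_FLOOR = 1e-16  # all logarithms are taken as log(max(p, LOG_FLOOR))

# factor names, in canonical order (affect omitted when disabled)
F_INTENTION = "intention"
F_CARD = "card"
F_DECISION = "decision"
F_AFFECT = "affect"
F_STAGE = "stage"

# modality names
M_ADVICE = "advice"
M_FEEDBACK = "feedback"
M_AROUSAL = "arousal"
M_CHOICE = "choice"

# outcome codings
ADVICE_BLUE, ADVICE_GREEN, ADVICE_NULL = 0, 1, 2
FB_CORRECT, FB_INCORRECT, FB_NULL = 0, 1, 2
CHOICE_NULL, CHOICE_BLUE, CHOICE_GREEN = 0, 1, 2
AROUSAL_LOW, AROUSAL_HIGH = 0, 1

# state codings within factors
S_TRUSTWORTHY, S_UNTRUSTWORTHY = 0, 1
S_BLUE, S_GREEN = 0, 1
D_NULL, D_BLUE, D_GREEN = 0, 1, 2
S_CALM, S_ANGRY = 0, 1
ST_START, ST_ADVICE, ST_FEEDBACK = 0, 1, 2

N_TIMESTEPS = 3
FEEDBACK_PREFERENCE = 3.0  # log-preference for 'correct' over neutral; 'incorrect' is -3


@dataclass(frozen=True)
class AgentConfig:
    """Free parameters of one agent.

    likelihood_precision
        Reliability ``a`` of the feedback mapping in the agent's model,
        in [0.5, 1].  Lower values make feedback less informative.
    habit_resistance
        Initial value ``e0`` of every Dirichlet habit count.  Large values
        dilute newly accumulated counts, preventing habit formation.
    mood
        Log-preference ``c`` for low over high arousal.  Negative values mean
        the agent expects to be aroused (negative mood).  Ignored when
        ``affect_enabled`` is False.
    choice_precision
        Softmax inverse temperature ``alpha`` over actions; affects only the
        stochasticity of enacted choices, never inference.
    policy_precision_prior
        Prior expectation ``1/beta`` of the policy precision ``gamma``.
    """

    likelihood_precision: float = 0.9
    habit_resistance: float = 2.0
    mood: float = 0.0
    choice_precision: float = 1.5
    policy_precision_prior: float = 1.0
    affect_enabled: bool = False
    seed: int = 0

    def __post_init__(self):
        a = self.likelihood_precision
        if not 0.5 <= a <= 1.0:
            raise ValueError(
                f"likelihood_precision must lie in [0.5, 1] (got {a}); values "
                "below 0.5 would invert the meaning of feedback")
        if self.habit_resistance <= 0:
            raise ValueError("habit_resistance must be positive")
        if self.choice_precision <= 0:
            raise ValueError("choice_precision must be positive")
        if self.policy_precision_prior <= 0:
            raise ValueError("policy_precision_prior must be positive")


@dataclass(frozen=True)
class Policy:
    """One policy: a trust stance crossed with a card choice.

    ``controls[factor]`` gives the control index applied to that factor at
    each of the two within-trial transitions.  The decision factor stays
    null until the final transition, which enacts the chosen card.
    """

    trust_action: int  # 0 trust, 1 distrust
    card_action: int   # 0 blue, 1 green
    controls: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        t = "trust" if self.trust_action == 0 else "distrust"
        k = "blue" if self.card_action == 0 else "green"
        return f"{t}-{k}"


def make_policies() -> list[Policy]:
    """The four policies {trust, distrust} x {blue, green}."""
    policies = []
    for t in (0, 1):
        for k in (0, 1):
            controls = {
                F_INTENTION: (t, t),
                F_CARD: (0, 0),
                F_DECISION: (0, 1 + k),  # stay null, then enact the card
                F_AFFECT: (t, t),
                F_STAGE: (0, 0),
            }
            policies.append(Policy(trust_action=t, card_action=k, controls=controls))
    return policies


@dataclass
class GenerativeModel:
    """The agent's arrays plus its mutable learning state (e, beta)."""

    config: AgentConfig
    factors: list            # factor names in order
    sizes: dict              # factor -> number of levels
    modalities: list         # modality names in order
    n_outcomes: dict         # modality -> number of outcome levels
    a: dict                  # modality -> likelihood array (No, *state dims)
    b: dict                  # factor -> transition array (n_controls, ns, ns)
    c: dict                  # modality -> log-preference vector (No,)
    d: dict                  # factor -> initial state prior (ns,)
    e: np.ndarray            # Dirichlet habit counts, one per policy
    policies: list = field(default_factory=make_policies)

    @property
    def alpha(self) -> float:
        return self.config.choice_precision

    @property
    def beta_prior(self) -> float:
        return 1.0 / self.config.policy_precision_prior

    @property
    def affect_enabled(self) -> bool:
        return self.config.affect_enabled

    @property
    def state_dims(self) -> tuple:
        return tuple(self.sizes[f] for f in self.factors)

    def habit_prior(self) -> np.ndarray:
        """Normalized prior over policies implied by the habit counts."""
        return self.e / self.e.sum()

    def policy_controls(self, policy: Policy) -> list:
        """Control index per factor (in model factor order) per transition."""
        return [tuple(policy.controls[f]) for f in self.factors]


def _advice_likelihood(dims: dict, factors: list) -> np.ndarray:
    """Advice is the correct card under a trustworthy advisor and the other
    card under an untrustworthy one, deterministically; null before the
    advice stage."""
    A = np.zeros((3,) + tuple(dims[f] for f in factors))
    for idx in np.ndindex(*A.shape[1:]):
        state = dict(zip(factors, idx))
        if state[F_STAGE] == ST_START:
            A[(ADVICE_NULL,) + idx] = 1.0
        else:
            advised = state[F_CARD] if state[F_INTENTION] == S_TRUSTWORTHY \
                else 1 - state[F_CARD]
            A[(advised,) + idx] = 1.0
    return A


def _feedback_likelihood(dims: dict, factors: list, precision: float) -> np.ndarray:
    """Feedback is 'correct' with probability ``precision`` when the enacted
    decision matches the correct card (and 'incorrect' with that probability
    on a mismatch); null before the feedback stage or without a decision."""
    A = np.zeros((3,) + tuple(dims[f] for f in factors))
    for idx in np.ndindex(*A.shape[1:]):
        state = dict(zip(factors, idx))
        if state[F_STAGE] != ST_FEEDBACK or state[F_DECISION] == D_NULL:
            A[(FB_NULL,) + idx] = 1.0
        else:
            match = (state[F_DECISION] - 1) == state[F_CARD]
            A[(FB_CORRECT,) + idx] = precision if match else 1 - precision
            A[(FB_INCORRECT,) + idx] = 1 - precision if match else precision
    return A


def _arousal_likelihood(dims: dict, factors: list) -> np.ndarray:
    """Deterministic interoception: calm -> low arousal, angry -> high."""
    A = np.zeros((2,) + tuple(dims[f] for f in factors))
    for idx in np.ndindex(*A.shape[1:]):
        state = dict(zip(factors, idx))
        o = AROUSAL_LOW if state[F_AFFECT] == S_CALM else AROUSAL_HIGH
        A[(o,) + idx] = 1.0
    return A


def _choice_likelihood(dims: dict, factors: list) -> np.ndarray:
    """Deterministic proprioception of the agent's own decision."""
    A = np.zeros((3,) + tuple(dims[f] for f in factors))
    for idx in np.ndindex(*A.shape[1:]):
        state = dict(zip(factors, idx))
        A[(state[F_DECISION],) + idx] = 1.0
    return A


def _transitions() -> dict:
    """Policy-conditioned transition arrays of the agent's model, indexed
    ``b[factor][control][next, previous]``."""
    b = {}
    # trusting makes the advisor trustworthy, distrusting untrustworthy
    b[F_INTENTION] = np.array([
        [[1.0, 1.0], [0.0, 0.0]],
        [[0.0, 0.0], [1.0, 1.0]],
    ])
    b[F_CARD] = np.eye(2)[None, :, :]
    # decision control maps every previous state to the controlled target
    dec = np.zeros((3, 3, 3))
    for u in range(3):
        dec[u, u, :] = 1.0
    b[F_DECISION] = dec
    b[F_AFFECT] = np.stack([AFFECT_TRANSITION["trust"], AFFECT_TRANSITION["distrust"]])
    stage = np.zeros((1, 3, 3))
    stage[0, ST_ADVICE, ST_START] = 1.0
    stage[0, ST_FEEDBACK, ST_ADVICE] = 1.0
    stage[0, ST_FEEDBACK, ST_FEEDBACK] = 1.0
    b[F_STAGE] = stage
    return b


def build_agent_model(config: AgentConfig) -> GenerativeModel:
    """Assemble the agent's generative model from its configuration.

    Each trial begins anew: the initial-state priors are uniform over the
    advisor's intention, the correct card and (when present) affect, and
    deterministic on decision = null and stage = start.  All trial-to-trial
    knowledge flows through the habit counts ``e`` and the precision prior
    ``beta``.
    """
    affect = config.affect_enabled
    factors = [F_INTENTION, F_CARD, F_DECISION] + ([F_AFFECT] if affect else []) \
        + [F_STAGE]
    sizes = {F_INTENTION: 2, F_CARD: 2, F_DECISION: 3, F_STAGE: 3}
    if affect:
        sizes[F_AFFECT] = 2
    modalities = [M_ADVICE, M_FEEDBACK] + ([M_AROUSAL] if affect else []) + [M_CHOICE]
    n_outcomes = {M_ADVICE: 3, M_FEEDBACK: 3, M_CHOICE: 3}
    if affect:
        n_outcomes[M_AROUSAL] = 2

    a = {
        M_ADVICE: _advice_likelihood(sizes, factors),
        M_FEEDBACK: _feedback_likelihood(sizes, factors, config.likelihood_precision),
        M_CHOICE: _choice_likelihood(sizes, factors),
    }
    if affect:
        a[M_AROUSAL] = _arousal_likelihood(sizes, factors)

    c = {
        M_ADVICE: np.zeros(3),
        M_FEEDBACK: np.array([FEEDBACK_PREFERENCE, -FEEDBACK_PREFERENCE, 0.0]),
        M_CHOICE: np.zeros(3),
    }
    if affect:
        c[M_AROUSAL] = np.array([config.mood, -config.mood])

    b = {f: arr for f, arr in _transitions().items() if f in factors}

    d = {
        F_INTENTION: np.array([0.5, 0.5]),
        F_CARD: np.array([0.5, 0.5]),
        F_DECISION: np.array([1.0, 0.0, 0.0]),
        F_STAGE: np.array([1.0, 0.0, 0.0]),
    }
    if affect:
        d[F_AFFECT] = np.array([0.5, 0.5])

    e = np.full(4, float(config.habit_resistance))
    return GenerativeModel(config=config, factors=factors, sizes=sizes,
                           modalities=modalities, n_outcomes=n_outcomes,
                           a=a, b=b, c=c, d=d, e=e)


@dataclass
class EnvironmentProcess:
    """The true generative process: the agent's arrays with feedback
    reliability pinned at 0.9 and an advisor transition that is a 10%
    per-trial flip rather than a controllable mapping."""

    sequence: TaskSequence
    affect_enabled: bool
    A: dict
    B: dict

    def agrees_with_agent_except(self, model: GenerativeModel) -> list:
        """Modalities/factors on which the true process and the agent's model
        differ (used by invariant tests)."""
        diffs = []
        for m in model.modalities:
            if m in self.A and not np.allclose(self.A[m], model.a[m]):
                diffs.append(m)
        for f in model.factors:
            if f in self.B and not np.allclose(self.B[f], model.b[f]):
                diffs.append(f)
        return diffs


def build_environment(sequence: TaskSequence,
                      affect_enabled: bool = False,
                      feedback_reliability: float = 1.0) -> EnvironmentProcess:
    """The world's arrays.  Identical to the agent's except: the feedback
    mapping is a truthful readout (whereas the agent models it with its
    likelihood precision ``a``), and the advisor's intention is not
    controllable -- it persists from its (flip-realized) trial-start value
    (the 10% flip itself acts across trials, relative to the schedule)."""
    factors = [F_INTENTION, F_CARD, F_DECISION] + \
        ([F_AFFECT] if affect_enabled else []) + [F_STAGE]
    sizes = {F_INTENTION: 2, F_CARD: 2, F_DECISION: 3, F_STAGE: 3}
    if affect_enabled:
        sizes[F_AFFECT] = 2
    A = {
        M_ADVICE: _advice_likelihood(sizes, factors),
        M_FEEDBACK: _feedback_likelihood(sizes, factors, feedback_reliability),
        M_CHOICE: _choice_likelihood(sizes, factors),
    }
    if affect_enabled:
        A[M_AROUSAL] = _arousal_likelihood(sizes, factors)
    B = {f: arr for f, arr in _transitions().items() if f in factors}
    # within a trial the realized intention persists, whatever the agent does
    B[F_INTENTION] = np.eye(2)[None, :, :]
    return EnvironmentProcess(sequence=sequence, affect_enabled=affect_enabled,
                              A=A, B=B)


def assert_column_stochastic(model: GenerativeModel, tol: float = 1e-10) -> None:
    """Every likelihood column (over outcomes) and transition column (over
    next states) must sum to one."""
    for m, arr in model.a.items():
        colsums = arr.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=tol):
            raise AssertionError(f"likelihood {m} is not column-stochastic")
    for f, arr in model.b.items():
        colsums = arr.sum(axis=1)
        if not np.allclose(colsums, 1.0, atol=tol):
            raise AssertionError(f"transition {f} is not column-stochastic")
    for f, vec in model.d.items():
        if not np.isclose(vec.sum(), 1.0, atol=tol):
            raise AssertionError(f"initial prior {f} does not normalize")
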