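"""Within-trial variational inference, policy selection and habit learning.

One trial runs over three timesteps.  At each timestep the agent

1. observes the outcomes the world emits (advice, feedback, its own choice,
   and arousal in affect models; modalities that have not happened yet are
   observed as explicit ``null`` outcomes),
2. infers policy-conditioned posteriors over all hidden-state factors at all
   three timesteps by coordinate-ascent (marginal message passing) on the
   variational free energy ``F``,
3. scores each policy's expected free energy ``G`` over the remaining,
   unobserved timesteps (risk relative to outcome preferences plus
   ambiguity, equivalently negative information gain minus expected
   log-preference),
4. solves the joint fixed point of the policy prior
   ``pi0 = softmax(ln E - gamma * G)``, the posterior
   ``pi = softmax(ln E - F - gamma * G)`` (``E`` the normalized Dirichlet
   habit vector) and the precision posterior
   ``beta_hat = beta + (pi - pi0) . G``, ``gamma = 1/beta_hat``; the prior
   rate ``beta`` stays fixed across trials (only the simulated treatment
   changes it), so precision fluctuates around ``1/beta`` — rising when
   evidence confirms the appealing policies and deflating when it
   contradicts them, which gates how far the appeal can push beliefs, and
5. enacts an action where one is due: the trust/distrust mental stance at
   the first timestep, the card choice at the second.  Actions are sampled
   from the softmax (at inverse temperature ``alpha``) of the log marginal
   policy probabilities, so ``alpha`` shapes behaviour but never inference.

At the final timestep no outcomes remain unobserved, so the start-of-trial
expected free energy ``G1`` persists as each policy's appeal in the final
posterior; the habit counts then accumulate that posterior.  Because a
trial's state inference depends only on the observations (habit counts and
precision enter policy selection, not state inference), posteriors and free
energies are memoized per observation pattern, of which a trial admits at
most a few dozen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task_environment as env
from .generative_model import (
    AgentConfig,
    GenerativeModel,
    LOG_FLOOR,
    M_ADVICE,
    M_AROUSAL,
    M_CHOICE,
    M_FEEDBACK,
    F_INTENTION,
    N_TIMESTEPS,
    S_TRUSTWORTHY,
    ADVICE_NULL,
    FB_NULL,
    CHOICE_NULL,
    build_agent_model,
)

logger = logging.getLogger("advisortask")

BETA_MIN = 0.05          # floor on the policy-precision rate parameter
VMP_MAX_SWEEPS = 16      # iteration cap for the coordinate-ascent updates
VMP_TOL = 1.0 / 128.0    # convergence tolerance on F, nats


def _ln(x: np.ndarray | float) -> np.ndarray:
    return np.log(np.maximum(x, LOG_FLOOR))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalized exponential; the sigma operator of policy selection."""
    z = x - np.max(x, axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


@dataclass
class BeliefState:
    """Inference products of one timestep of one trial."""

    state_posteriors: list          # per policy: {factor: (T, ns) array}
    policy_prior: np.ndarray        # pi0
    policy_posterior: np.ndarray    # pi
    F: np.ndarray                   # variational free energy per policy, nats
    G: np.ndarray                   # expected free energy per policy, nats
    gamma: float
    beta_posterior: float
    bma: dict = field(default_factory=dict)   # policy-averaged {factor: (T, ns)}


@dataclass
class TrialRecord:
    """Observable trace of one trial."""

    trial_index: int
    advice: int                     # 0 blue, 1 green
    choice: int                     # 0 blue, 1 green
    feedback: int                   # 0 correct, 1 incorrect
    arousal: int | None             # trial-start arousal reading, None without affect
    true_intention: int             # realized (post-flip) advisor state
    correct_card: int
    trust_action: int               # enacted stance, 0 trust / 1 distrust
    prior_trust: float              # BMA P(trustworthy) before any observation
    posterior_trust: float          # BMA P(trustworthy) at the final timestep
    trust_action_posterior: float   # final posterior mass on trust policies
    gamma_T: float
    habit_counts_snapshot: np.ndarray


class TrialInference:
    """Vectorized marginal message passing for all policies of one agent.

    Solutions are cached per observation pattern: state inference depends
    only on the observations and the (fixed) likelihood/transition arrays,
    never on the evolving habit counts or precision.
    """

    def __init__(self, model: GenerativeModel):
        self.model = model
        self.factors = model.factors
        self.nf = len(self.factors)
        self.P = len(model.policies)
        self.dims = model.state_dims
        letters = "abcdefgh"[: self.nf]
        self._letters = letters

        self.ln_a = {m: _ln(model.a[m]) for m in model.modalities}
        self.ln_d = [_ln(model.d[f]) for f in self.factors]
        # ambiguity H(o|s) per modality over the joint state space
        self.H = {m: -(model.a[m] * self.ln_a[m]).sum(axis=0)
                  for m in model.modalities}

        # policy-stacked log transitions: (P, n_transitions, ns, ns)
        self.ln_b = []
        for fi, f in enumerate(self.factors):
            arr = np.empty((self.P, N_TIMESTEPS - 1,
                            model.sizes[f], model.sizes[f]))
            for p, pol in enumerate(model.policies):
                for tr in range(N_TIMESTEPS - 1):
                    u = pol.controls[f][tr]
                    arr[p, tr] = _ln(model.b[f][u])
            self.ln_b.append(arr)
        self._b = []
        for fi, f in enumerate(self.factors):
            arr = np.empty_like(self.ln_b[fi])
            for p, pol in enumerate(model.policies):
                for tr in range(N_TIMESTEPS - 1):
                    arr[p, tr] = model.b[f][pol.controls[f][tr]]
            self._b.append(arr)

        # einsum scripts: message to factor fi from a full-joint array
        self._msg_script = [
            letters + "," + ",".join("p" + letters[g] for g in range(self.nf)
                                     if g != fi) + "->p" + letters[fi]
            for fi in range(self.nf)]
        self._full_script = letters + "," + ",".join(
            "p" + letters[g] for g in range(self.nf)) + "->p"
        self._qo_script = "o" + letters + "," + ",".join(
            "p" + letters[g] for g in range(self.nf)) + "->po"

        self._cache: dict = {}

    # -- core solver ----------------------------------------------------

    def _init_Q(self) -> list:
        """Forward-propagated priors: the prior-predictive marginals."""
        Q = []
        for fi, f in enumerate(self.factors):
            q = np.empty((self.P, N_TIMESTEPS, self.model.sizes[f]))
            q[:, 0] = self.model.d[f][None, :]
            for tau in range(1, N_TIMESTEPS):
                q[:, tau] = np.einsum("pij,pj->pi", self._b[fi][:, tau - 1],
                                      q[:, tau - 1])
            Q.append(q)
        return Q

    def _free_energy(self, Q: list, obs: tuple) -> np.ndarray:
        F = np.zeros(self.P)
        for fi in range(self.nf):
            q = Q[fi]
            F += (q * _ln(q)).sum(axis=(1, 2))                    # -entropy
            F -= q[:, 0] @ self.ln_d[fi]                          # prior
            for tau in range(1, N_TIMESTEPS):
                F -= np.einsum("pi,pij,pj->p", q[:, tau],
                               self.ln_b[fi][:, tau - 1], q[:, tau - 1])
        for tau, omap in enumerate(obs):
            for m, o in omap:
                ops = [self.ln_a[m][o]] + [Q[g][:, tau] for g in range(self.nf)]
                F -= np.einsum(self._full_script, *ops)
        return F

    def _solve(self, obs: tuple) -> tuple[list, np.ndarray]:
        """Coordinate ascent to a fixed point of the mean-field updates."""
        Q = self._init_Q()
        F = self._free_energy(Q, obs)
        for sweep in range(VMP_MAX_SWEEPS):
            for tau in range(N_TIMESTEPS):
                omap = obs[tau] if tau < len(obs) else ()
                for fi in range(self.nf):
                    lnq = np.zeros((self.P, self.model.sizes[self.factors[fi]]))
                    for m, o in omap:
                        ops = [self.ln_a[m][o]] + [Q[g][:, tau]
                                                   for g in range(self.nf) if g != fi]
                        lnq += np.einsum(self._msg_script[fi], *ops)
                    if tau == 0:
                        lnq += self.ln_d[fi][None, :]
                    else:
                        lnq += np.einsum("pij,pj->pi", self.ln_b[fi][:, tau - 1],
                                         Q[fi][:, tau - 1])
                    if tau < N_TIMESTEPS - 1:
                        lnq += np.einsum("pij,pi->pj", self.ln_b[fi][:, tau],
                                         Q[fi][:, tau + 1])
                    Q[fi][:, tau] = softmax(lnq)
            F_new = self._free_energy(Q, obs)
            if np.max(np.abs(F_new - F)) < VMP_TOL:
                F = F_new
                break
            F = F_new
        else:
            logger.warning("state inference did not converge within %d sweeps",
                           VMP_MAX_SWEEPS)
        return Q, F

    def _expected_free_energy(self, Q: list, n_observed: int) -> np.ndarray:
        """Risk plus ambiguity over the unobserved future timesteps.

        Arousal is a once-per-trial interoceptive reading (taken at the
        start of each trial, reflecting the previously adopted stance), so
        each policy anticipates exactly one arousal consequence: the
        arousal modality contributes at the first future timestep only.
        The exteroceptive modalities contribute at every future timestep.
        """
        G = np.zeros(self.P)
        for tau in range(n_observed, N_TIMESTEPS):
            qs = [Q[g][:, tau] for g in range(self.nf)]
            for m in self.model.modalities:
                if m == M_AROUSAL and tau != n_observed:
                    continue
                qo = np.einsum(self._qo_script, self.model.a[m], *qs)
                G += (qo * (_ln(qo) - self.model.c[m][None, :])).sum(axis=1)
                G += np.einsum(self._full_script, self.H[m], *qs)
        return G

    def evaluate(self, obs: tuple) -> tuple[list, np.ndarray, np.ndarray]:
        """Posteriors, F and G for an observation pattern (memoized).

        ``obs`` is a tuple over observed timesteps of tuples of
        ``(modality, outcome index)`` pairs.
        """
        key = obs
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Q, F = self._solve(obs)
        G = self._expected_free_energy(Q, len(obs))
        self._cache[key] = (Q, F, G)
        return Q, F, G


# -- single-policy convenience surface ----------------------------------


def infer_states(model: GenerativeModel, observations_so_far, policy):
    """Policy-conditioned state posteriors and variational free energy.

    ``observations_so_far`` is a sequence (one entry per observed timestep)
    of mappings from modality name to outcome index.

    Returns ``({factor: (T, ns) array}, F)``.
    """
    sub = GenerativeModel(config=model.config, factors=model.factors,
                          sizes=model.sizes, modalities=model.modalities,
                          n_outcomes=model.n_outcomes, a=model.a, b=model.b,
                          c=model.c, d=model.d, e=model.e, policies=[policy])
    engine = TrialInference(sub)
    obs = tuple(tuple(sorted(omap.items())) for omap in observations_so_far)
    Q, F = engine._solve(obs)
    posts = {f: Q[fi][0] for fi, f in enumerate(model.factors)}
    return posts, float(F[0])


def expected_free_energy(model: GenerativeModel, state_posteriors, policy,
                         n_observed: int = 0) -> float:
    """Expected free energy of one policy over timesteps >= ``n_observed``."""
    sub = GenerativeModel(config=model.config, factors=model.factors,
                          sizes=model.sizes, modalities=model.modalities,
                          n_outcomes=model.n_outcomes, a=model.a, b=model.b,
                          c=model.c, d=model.d, e=model.e, policies=[policy])
    engine = TrialInference(sub)
    Q = [np.asarray(state_posteriors[f])[None, ...] for f in model.factors]
    return float(engine._expected_free_energy(Q, n_observed)[0])


def policy_distributions(G: np.ndarray, F: np.ndarray, e: np.ndarray,
                         gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Prior and posterior over policies.

    ``pi0 = softmax(ln E - gamma G)`` and ``pi = softmax(ln E - F - gamma G)``
    with ``E = e / sum(e)`` the habit prior.
    """
    lnE = _ln(np.asarray(e, dtype=float) / np.sum(e))
    pi0 = softmax(lnE - gamma * np.asarray(G))
    pi = softmax(lnE - np.asarray(F) - gamma * np.asarray(G))
    return pi0, pi


def update_precision(beta_prior: float, pi: np.ndarray, pi0: np.ndarray,
                     G: np.ndarray) -> tuple[float, float]:
    """``beta_hat = beta + (pi - pi0) . G`` (floored), ``gamma = 1/beta_hat``.

    Precision rises when the posterior shifts toward low-G policies, i.e.
    when events unfold as the agent's preferences and predictions anticipate.
    """
    beta_post = float(beta_prior + (np.asarray(pi) - np.asarray(pi0)) @ np.asarray(G))
    beta_post = max(beta_post, BETA_MIN)
    return beta_post, 1.0 / beta_post


def precision_fixed_point(G: np.ndarray, F: np.ndarray, e: np.ndarray,
                          beta_prior: float, max_iter: int = 32,
                          tol: float = 1e-6):
    """Joint variational fixed point of the policy posterior and precision.

    ``pi``, ``pi0`` and ``gamma`` are mutually dependent: the posterior is
    formed at precision ``gamma``, and the precision posterior responds to
    how far the evidence moved the posterior away from (or toward) the
    low-G policies.  Iterating the two updates to convergence makes the
    precision self-gating: evidence that contradicts the gamma-weighted
    policy appeal deflates gamma within the trial (so the appeal cannot
    override strong disconfirming evidence), while confirming evidence
    sustains or inflates it.

    Returns ``(pi0, pi, beta_post, gamma)``.
    """
    beta_post = float(beta_prior)
    pi0 = pi = None
    for _ in range(max_iter):
        gamma = 1.0 / beta_post
        pi0, pi = policy_distributions(G, F, e, gamma)
        target, _ = update_precision(beta_prior, pi, pi0, G)
        new = beta_post + 0.5 * (target - beta_post)  # damped update
        if abs(new - beta_post) < tol:
            beta_post = new
            break
        beta_post = new
    gamma = 1.0 / max(beta_post, BETA_MIN)
    pi0, pi = policy_distributions(G, F, e, gamma)
    return pi0, pi, max(beta_post, BETA_MIN), gamma


def bma_states(state_posteriors: list, pi: np.ndarray) -> dict:
    """Bayesian model average of per-policy posteriors under ``pi``."""
    out = {}
    first = state_posteriors[0]
    for f in first:
        stacked = np.stack([sp[f] for sp in state_posteriors])  # (P, T, ns)
        out[f] = np.einsum("p,pts->ts", np.asarray(pi), stacked)
    return out


def action_marginal(pi: np.ndarray, policies, dimension: str) -> np.ndarray:
    """Marginal probability of each action along one control dimension
    ('trust' or 'card'), summing policy mass over policies sharing it."""
    attr = "trust_action" if dimension == "trust" else "card_action"
    p = np.zeros(2)
    for prob, pol in zip(pi, policies):
        p[getattr(pol, attr)] += prob
    return p


def select_action(p_u: np.ndarray, alpha: float,
                  rng: np.random.Generator) -> int:
    """Sample an action from ``softmax(alpha * ln p(u))``."""
    probs = softmax(alpha * _ln(p_u))
    return int(rng.choice(len(p_u), p=probs))


def update_habits(e: np.ndarray, pi_final: np.ndarray) -> np.ndarray:
    """Accumulate the final policy posterior into the Dirichlet counts:
    a full count when the chosen policy is certain, otherwise mass
    proportional to the posterior probability that each policy was chosen."""
    return e + np.asarray(pi_final)


# -- trial and run loops ------------------------------------------------


@dataclass
class TrialContext:
    """The world's realization of one trial."""

    trial_index: int
    true_intention: int
    correct_card: int


@dataclass
class AgentState:
    """Mutable across-trial state: the model (habit counts live on it), the
    policy-precision prior rate ``beta`` (fixed unless treated), the latest
    posterior rate ``beta_post``, and the world's slow affect state (the
    interoceptive residue of the previously adopted stance)."""

    model: GenerativeModel
    engine: TrialInference
    beta: float
    beta_post: float
    env_affect: int | None = None

    @classmethod
    def fresh(cls, config: AgentConfig) -> "AgentState":
        model = build_agent_model(config)
        return cls(model=model, engine=TrialInference(model),
                   beta=model.beta_prior, beta_post=model.beta_prior)


def _null_obs(affect: bool, arousal: int | None):
    base = [(M_ADVICE, ADVICE_NULL), (M_FEEDBACK, FB_NULL), (M_CHOICE, CHOICE_NULL)]
    if affect:
        base.append((M_AROUSAL, arousal))
    return tuple(sorted(base))


def run_trial(state: AgentState, ctx: TrialContext, rng: np.random.Generator,
              replay_actions: tuple[int, int] | None = None,
              return_beliefs: bool = False):
    """Execute one three-timestep trial and update habits and precision.

    ``replay_actions`` forces the (trust, card) actions without consuming
    random draws, for deterministic replay.
    """
    model = state.model
    engine = state.engine
    affect = model.affect_enabled
    intention_idx = model.factors.index(F_INTENTION)

    # world state at timestep 1: arousal reads out the affect state left by
    # the previously adopted stance (uniform at the start of a run)
    arousal = None
    if affect:
        if state.env_affect is None:
            state.env_affect = int(rng.random() < 0.5)
        arousal = env.emit_arousal(state.env_affect)

    # timestep 1: only null placeholders (and arousal) are available
    obs1 = (_null_obs(affect, arousal if affect else None),)
    Q1, F1, G1 = engine.evaluate(obs1)
    pi0_1, pi_1, state.beta_post, gamma = precision_fixed_point(
        G1, F1, model.e, state.beta)
    prior_trust = float(sum(
        p0 * Q1[intention_idx][pi, N_TIMESTEPS - 1, S_TRUSTWORTHY]
        for pi, p0 in enumerate(pi0_1)))

    if replay_actions is None:
        trust_action = select_action(
            action_marginal(pi_1, model.policies, "trust"), model.alpha, rng)
    else:
        trust_action = replay_actions[0]

    # world: advice appears; the enacted stance drives the (slow) affective
    # response that will be felt as arousal on the next trial
    advice = ctx.correct_card if ctx.true_intention == env.TRUSTWORTHY \
        else 1 - ctx.correct_card
    if affect:
        state.env_affect = env.sample_affect(trust_action, rng)

    obs2_map = [(M_ADVICE, advice), (M_FEEDBACK, FB_NULL), (M_CHOICE, CHOICE_NULL)]
    obs2 = obs1 + (tuple(sorted(obs2_map)),)
    Q2, F2, G2 = engine.evaluate(obs2)
    pi0_2, pi_2, state.beta_post, gamma = precision_fixed_point(
        G2, F2, model.e, state.beta)

    if replay_actions is None:
        choice = select_action(
            action_marginal(pi_2, model.policies, "card"), model.alpha, rng)
    else:
        choice = replay_actions[1]

    # world: truthful feedback on the choice
    feedback = env.emit_feedback(choice, ctx.correct_card, rng)

    obs3_map = [(M_ADVICE, advice), (M_FEEDBACK, feedback),
                (M_CHOICE, 1 + choice)]
    obs3 = obs2 + (tuple(sorted(obs3_map)),)
    Q3, F3, _ = engine.evaluate(obs3)
    # The start-of-trial expected free energy G1 persists as each policy's
    # appeal: the final posterior combines habits, accumulated evidence and
    # the gamma-weighted appeal.  (No outcomes remain unobserved, so no new
    # G is computable at the final timestep.)
    pi0_3, pi_3, state.beta_post, gamma = precision_fixed_point(
        G1, F3, model.e, state.beta)

    posterior_trust = float(sum(
        p * Q3[intention_idx][pi, N_TIMESTEPS - 1, S_TRUSTWORTHY]
        for pi, p in enumerate(pi_3)))
    trust_action_posterior = float(action_marginal(pi_3, model.policies, "trust")[0])

    model.e = update_habits(model.e, pi_3)

    record = TrialRecord(
        trial_index=ctx.trial_index, advice=advice, choice=choice,
        feedback=feedback, arousal=arousal,
        true_intention=ctx.true_intention, correct_card=ctx.correct_card,
        trust_action=trust_action, prior_trust=prior_trust,
        posterior_trust=posterior_trust,
        trust_action_posterior=trust_action_posterior,
        gamma_T=gamma, habit_counts_snapshot=model.e.copy())
    if not return_beliefs:
        return record
    posts = [{f: Q3[fi][p] for fi, f in enumerate(model.factors)}
             for p in range(len(model.policies))]
    belief = BeliefState(state_posteriors=posts, policy_prior=pi0_3,
                         policy_posterior=pi_3, F=F3, G=G1, gamma=gamma,
                         beta_posterior=state.beta_post,
                         bma=bma_states(posts, pi_3))
    return record, belief


def run_agent(config: AgentConfig, sequence: env.TaskSequence,
              n_trials: int | None = None, treatment: bool = False,
              replay: list | None = None) -> list[TrialRecord]:
    """Run one agent for ``n_trials`` (default: the sequence length),
    carrying habits and precision across trials.

    ``treatment`` applies the simulated antipsychotic: once the agent has
    made 10 false posterior inferences about the realized trustworthiness,
    its policy precision ``1/beta`` is halved toward the population minimum
    of 0.25, once, between trials.

    ``replay`` forces the per-trial (trust, card) actions, bypassing action
    sampling while leaving every other random draw in place.
    """
    if n_trials is None:
        n_trials = sequence.n_trials
    state = AgentState.fresh(config)
    rng = np.random.default_rng(config.seed)
    records: list[TrialRecord] = []
    n_false = 0
    treated = False
    for t in range(n_trials):
        true_intention, _ = env.realize_trial(sequence, t, rng)
        ctx = TrialContext(trial_index=t, true_intention=true_intention,
                           correct_card=int(sequence.correct_card[t]))
        rec = run_trial(state, ctx, rng,
                        replay_actions=(replay[t] if replay is not None else None))
        records.append(rec)
        p_true = rec.posterior_trust if true_intention == env.TRUSTWORTHY \
            else 1.0 - rec.posterior_trust
        if p_true < 0.5:
            n_false += 1
        if treatment and not treated and n_false >= 10:
            inv = apply_treatment(1.0 / state.beta)
            state.beta = 1.0 / inv
            treated = True
    return records


def apply_treatment(inv_beta_current: float, floor: float = 0.25) -> float:
    """Simulated antipsychotic: ``1/beta* = (1/beta - 0.25) * 0.5 + 0.25``.

    Halves policy precision toward the population minimum; the minimum
    itself is a fixed point.
    """
    return (inv_beta_current - floor) * 0.5 + floor


# -- record serialization ----------------------------------------------


def records_to_dataframe(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "trial": r.trial_index,
            "advice": r.advice, "choice": r.choice, "feedback": r.feedback,
            "arousal": r.arousal if r.arousal is not None else "",
            "true_intention": r.true_intention,
            "correct_card": r.correct_card,
            "trust_action": r.trust_action,
            "prior_trust": r.prior_trust,
            "posterior_trust": r.posterior_trust,
            "trust_action_posterior": r.trust_action_posterior,
            "gamma_T": r.gamma_T,
            "e_trust_blue": r.habit_counts_snapshot[0],
            "e_trust_green": r.habit_counts_snapshot[1],
            "e_distrust_blue": r.habit_counts_snapshot[2],
            "e_distrust_green": r.habit_counts_snapshot[3],
        })
    return pd.DataFrame(rows)


def save_run(records: list[TrialRecord], config: AgentConfig, csv_path,
             sidecar_path=None) -> None:
    """One CSV row per trial plus a JSON sidecar with the configuration and
    the final habit counts and precision rate."""
    df = records_to_dataframe(records)
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        final = records[-1]
        payload = {
            "config": {
                "a": config.likelihood_precision,
                "e0": config.habit_resistance,
                "mood": config.mood,
                "alpha": config.choice_precision,
                "inv_beta": config.policy_precision_prior,
                "affect": config.affect_enabled,
                "seed": config.seed,
            },
            "final_e": list(map(float, final.habit_counts_snapshot)),
            "final_gamma": final.gamma_T,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2)
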