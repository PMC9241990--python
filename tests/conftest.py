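import numpy as np
import pytest

from advisortask import AgentConfig, build_agent_model, make_sequence


@pytest.fixture
def base_config():
    """The canonical well-functioning agent (high likelihood precision,
    habit-forming, neutral mood)."""
    return AgentConfig(likelihood_precision=0.9, habit_resistance=2.0,
                       policy_precision_prior=1.0, choice_precision=1.5,
                       seed=0)


@pytest.fixture
def affect_config():
    return AgentConfig(likelihood_precision=0.75, habit_resistance=2.0,
                       mood=-1.0, policy_precision_prior=1.0,
                       choice_precision=1.5, affect_enabled=True, seed=0)


@pytest.fixture
def model(base_config):
    return build_agent_model(base_config)


@pytest.fixture
def affect_model(affect_config):
    return build_agent_model(affect_config)


@pytest.fixture
def trustworthy_sequence():
    return make_sequence("consistently_trustworthy", seed=3)


@pytest.fixture
def changing_sequence():
    return make_sequence("changing_trustworthiness", initial_consistency=125,
                         seed=3)


def exact_joint_posterior(model, observations, policy):
    """Independent oracle: exact posterior over hidden-state trajectories by
    brute-force enumeration of the full joint state space at each timestep.

    Enumerates every combination of joint states (s_1, s_2, s_3), scores it
    under the priors, the policy's transitions and the observed likelihoods,
    and normalizes by summation.  Returns per-factor, per-timestep marginals
    and the exact negative log evidence -ln p(o).
    """
    factors = model.factors
    dims = [model.sizes[f] for f in factors]
    joint_states = list(np.ndindex(*dims))
    n = len(joint_states)

    def lik(tau, s):
        p = 1.0
        if tau < len(observations):
            for m, o in observations[tau].items():
                p *= model.a[m][(o,) + tuple(s)]
        return p

    prior = np.array([np.prod([model.d[f][s[i]] for i, f in enumerate(factors)])
                      for s in joint_states])
    trans = []
    for tr in range(2):
        T = np.empty((n, n))
        for j, sj in enumerate(joint_states):
            for i, si in enumerate(joint_states):
                p = 1.0
                for fi, f in enumerate(factors):
                    u = policy.controls[f][tr]
                    p *= model.b[f][u][si[fi], sj[fi]]
                T[i, j] = p
        trans.append(T)

    L = [np.array([lik(tau, s) for s in joint_states]) for tau in range(3)]
    # joint over (s1, s2, s3) by explicit summation
    w1 = prior * L[0]
    joint12 = trans[0] * w1[None, :]          # [s2, s1]
    joint12 *= L[1][:, None]
    joint123 = np.einsum("ij,jk->ijk", trans[1], joint12)  # [s3, s2, s1]
    joint123 *= L[2][:, None, None]
    Z = joint123.sum()
    if Z == 0.0:
        # the observation stream is impossible under this policy
        return None, np.inf
    marg = {
        0: joint123.sum(axis=(0, 1)) / Z,   # axes are [s3, s2, s1]
        1: joint123.sum(axis=(0, 2)) / Z,
        2: joint123.sum(axis=(1, 2)) / Z,
    }
    out = {}
    for fi, f in enumerate(factors):
        per_tau = np.zeros((3, dims[fi]))
        for tau in range(3):
            flat = marg[tau]
            for s_idx, s in enumerate(joint_states):
                per_tau[tau, s[fi]] += flat[s_idx]
        out[f] = per_tau
    return out, -np.log(Z)
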