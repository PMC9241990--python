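import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import advisortask as at
from advisortask.generative_model import (
    ADVICE_NULL,
    CHOICE_NULL,
    FB_NULL,
    M_ADVICE,
    M_CHOICE,
    M_FEEDBACK,
    build_agent_model,
    make_policies,
)
from advisortask.inference_engine import (
    BETA_MIN,
    action_marginal,
    bma_states,
    policy_distributions,
    softmax,
    update_precision,
)
from conftest import exact_joint_posterior


def _observations(advice, choice, feedback):
    """The full three-timestep observation stream of a no-affect trial."""
    return [
        {M_ADVICE: ADVICE_NULL, M_FEEDBACK: FB_NULL, M_CHOICE: CHOICE_NULL},
        {M_ADVICE: advice, M_FEEDBACK: FB_NULL, M_CHOICE: CHOICE_NULL},
        {M_ADVICE: advice, M_FEEDBACK: feedback, M_CHOICE: 1 + choice},
    ]


class TestInferStatesAgainstEnumerationOracle:
    """The coordinate-ascent posteriors must match exact brute-force
    enumeration over the joint hidden-state space (<= 72 states/timestep)."""

    @pytest.mark.parametrize("a", [0.6, 0.75, 0.9])
    @pytest.mark.parametrize("advice,choice,feedback", [
        (0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 1),
    ])
    def test_full_trial_posteriors(self, a, advice, choice, feedback):
        model = build_agent_model(at.AgentConfig(likelihood_precision=a))
        obs = _observations(advice, choice, feedback)
        for policy in model.policies:
            post, F = at.infer_states(model, obs, policy)
            exact, neg_log_evidence = exact_joint_posterior(model, obs, policy)
            if exact is None:
                # the observations rule this policy out; its free energy
                # must be enormous so it carries no posterior mass
                assert F > 30.0, (policy.label, F)
                continue
            for f in model.factors:
                tv = 0.5 * np.abs(post[f] - exact[f]).sum(axis=1).max()
                assert tv < 1e-3, (policy.label, f, tv)

    def test_partial_observations(self, model):
        obs = _observations(0, 0, 0)[:2]  # advice seen, no choice yet
        for policy in model.policies:
            post, _ = at.infer_states(model, obs, policy)
            exact, _ = exact_joint_posterior(model, obs, policy)
            for f in model.factors:
                tv = 0.5 * np.abs(post[f] - exact[f]).sum(axis=1).max()
                assert tv < 1e-3

    def test_posterior_matches_single_factor_bayes(self):
        # a = 0.9, chose blue, feedback correct: the card posterior under the
        # trust-blue policy equals a 0.9/0.1 likelihood update of the
        # uniform card prior combined with the (deterministic) advice
        model = build_agent_model(at.AgentConfig(likelihood_precision=0.9))
        trust_blue = model.policies[0]
        obs = _observations(0, 0, 0)
        post, _ = at.infer_states(model, obs, trust_blue)
        # advice blue under trust pins the card to blue
        assert post["card"][2, 0] > 0.999

    def test_flat_feedback_likelihood_leaves_card_at_advice_prior(self):
        # a = 0.5 makes feedback uninformative: the card posterior under a
        # policy is set by the advice alone
        model = build_agent_model(at.AgentConfig(likelihood_precision=0.5))
        obs = _observations(0, 1, 1)
        for policy in model.policies:
            exact, _ = exact_joint_posterior(model, obs, policy)
            if exact is None:
                continue  # ruled out by the observed choice
            post, _ = at.infer_states(model, obs, policy)
            assert np.allclose(post["card"], exact["card"], atol=1e-3)


class TestExpectedFreeEnergy:
    def test_zero_for_deterministic_world_without_preferences(self):
        # neutral preferences and fully determined states: no risk, no
        # ambiguity, no information to gain
        model = build_agent_model(at.AgentConfig(likelihood_precision=0.99))
        for m in model.c:
            model.c[m] = np.zeros_like(model.c[m])
        policy = model.policies[0]
        obs = _observations(0, 0, 0)
        post, _ = at.infer_states(model, obs, policy)
        G = at.expected_free_energy(model, post, policy, n_observed=3)
        assert G == pytest.approx(0.0, abs=1e-12)

    def test_preferred_outcome_lowers_G_by_preference_gap(self):
        # two policies with identical predicted states except that one
        # predicts 'correct' feedback (+3) and the other 'incorrect' (-3):
        # ~6 nats of difference
        model = build_agent_model(at.AgentConfig(likelihood_precision=0.99))
        obs = _observations(0, 0, 0)[:2]  # advice blue observed
        trust_blue, trust_green = model.policies[0], model.policies[1]
        post_b, _ = at.infer_states(model, obs, trust_blue)
        post_g, _ = at.infer_states(model, obs, trust_green)
        G_b = at.expected_free_energy(model, post_b, trust_blue, n_observed=2)
        G_g = at.expected_free_energy(model, post_g, trust_green, n_observed=2)
        assert G_g - G_b == pytest.approx(6.0, abs=0.2)

    def test_matches_hand_computed_risk_plus_ambiguity(self):
        # toy check on the feedback modality alone: risk + ambiguity under
        # the trust-blue policy after blue advice, a = 0.75
        a = 0.75
        model = build_agent_model(at.AgentConfig(likelihood_precision=a))
        for m in (M_ADVICE, M_CHOICE):
            model.c[m] = np.zeros_like(model.c[m])
        obs = _observations(0, 0, 0)[:2]
        policy = model.policies[0]
        post, _ = at.infer_states(model, obs, policy)
        G = at.expected_free_energy(model, post, policy, n_observed=2)
        qo = np.array([a, 1 - a, 0.0])
        c = np.array([3.0, -3.0, 0.0])
        with np.errstate(divide="ignore", invalid="ignore"):
            risk = np.nansum(qo * (np.log(qo) - c))
        ambiguity = -(a * np.log(a) + (1 - a) * np.log(1 - a))
        assert G == pytest.approx(risk + ambiguity, abs=1e-3)


class TestPolicyDistributions:
    def test_uniform_under_symmetry(self):
        pi0, pi = policy_distributions(np.zeros(4), np.zeros(4),
                                       np.ones(4), gamma=1.0)
        assert np.allclose(pi0, 0.25) and np.allclose(pi, 0.25)

    def test_softmax_arithmetic(self):
        # G = [0, 1], gamma = 1, flat habits and F: pi = sigma([0, -1])
        pi0, pi = policy_distributions(np.array([0.0, 1.0]), np.zeros(2),
                                       np.ones(2), gamma=1.0)
        assert np.allclose(pi, [0.7311, 0.2689], atol=1e-4)
        assert np.allclose(pi0, pi)

    def test_habit_resistance_leaves_prior_at_softmax_of_G(self):
        # 250 counts on one policy barely move the prior when e0 = 599
        G = np.array([0.0, 0.5, 1.0, 1.5])
        e = np.full(4, 599.0)
        e[0] += 250
        pi0, _ = policy_distributions(G, np.zeros(4), e, gamma=1.0)
        ref = softmax(-G)
        assert np.abs(pi0 - ref).max() < 0.1


class TestPrecisionUpdate:
    def test_no_innovation_no_change(self):
        pi = np.array([0.4, 0.6])
        beta, gamma = update_precision(1.3, pi, pi, np.array([2.0, 5.0]))
        assert beta == pytest.approx(1.3)
        assert gamma == pytest.approx(1 / 1.3)

    def test_arithmetic_oracle(self):
        # beta_hat = 1 + (0.3*1 - 0.3*2) = 0.7
        beta, gamma = update_precision(
            1.0, np.array([0.8, 0.2]), np.array([0.5, 0.5]),
            np.array([1.0, 2.0]))
        assert beta == pytest.approx(0.7)
        assert gamma == pytest.approx(1 / 0.7)

    def test_shift_toward_low_G_raises_gamma(self):
        beta, gamma = update_precision(
            1.0, np.array([0.9, 0.1]), np.array([0.5, 0.5]),
            np.array([0.0, 3.0]))
        assert beta < 1.0 and gamma > 1.0

    def test_floor(self):
        beta, _ = update_precision(0.1, np.array([1.0, 0.0]),
                                   np.array([0.0, 1.0]), np.array([0.0, 9.0]))
        assert beta == BETA_MIN


class TestBMA:
    def test_single_policy_identity(self):
        posts = [{"card": np.array([[0.2, 0.8], [0.6, 0.4], [1.0, 0.0]])}]
        out = bma_states(posts, np.array([1.0]))
        assert np.allclose(out["card"], posts[0]["card"])

    def test_symmetric_mixture(self):
        a = {"f": np.array([[1.0, 0.0]])}
        b = {"f": np.array([[0.0, 1.0]])}
        out = bma_states([a, b], np.array([0.5, 0.5]))
        assert np.allclose(out["f"], [[0.5, 0.5]])

    def test_three_policy_weighted_sum(self):
        rng = np.random.default_rng(0)
        posts = []
        for _ in range(3):
            q = rng.random((2, 3))
            q /= q.sum(axis=1, keepdims=True)
            posts.append({"f": q})
        w = np.array([0.2, 0.3, 0.5])
        out = bma_states(posts, w)
        ref = sum(wi * p["f"] for wi, p in zip(w, posts))
        assert np.allclose(out["f"], ref)


class TestActionSelection:
    def test_marginalization_over_policies(self):
        policies = make_policies()
        pi = np.array([0.3, 0.3, 0.2, 0.2])  # trust-blue/green, distrust-b/g
        p = action_marginal(pi, policies, "trust")
        assert np.allclose(p, [0.6, 0.4])

    def test_high_alpha_limit_is_greedy(self):
        rng = np.random.default_rng(0)
        picks = [at.select_action(np.array([0.9, 0.1]), 50.0, rng)
                 for _ in range(200)]
        assert all(p == 0 for p in picks)

    def test_alpha_one_recovers_marginal_frequencies(self):
        rng = np.random.default_rng(1)
        p = np.array([0.7, 0.3])
        n = 10_000
        ones = sum(at.select_action(p, 1.0, rng) for _ in range(n))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(ones / n - 0.3) < 3 * se


class TestHabits:
    def test_certain_choice_gains_full_count(self):
        e = at.update_habits(np.full(4, 2.0), np.array([1.0, 0, 0, 0]))
        assert np.allclose(e, [3, 2, 2, 2])

    def test_uncertain_choice_gains_proportional_mass(self):
        e = at.update_habits(np.full(4, 2.0), np.full(4, 0.25))
        assert np.allclose(e, 2.25)

    def test_counts_never_decrease_over_a_run(self, base_config,
                                              trustworthy_sequence):
        records = at.run_agent(base_config, trustworthy_sequence, n_trials=40)
        prev = np.full(4, base_config.habit_resistance)
        for r in records:
            assert (r.habit_counts_snapshot >= prev - 1e-12).all()
            prev = r.habit_counts_snapshot


class TestRunLoop:
    def test_record_stream_is_complete_and_consistent(self, base_config,
                                                      trustworthy_sequence):
        records = at.run_agent(base_config, trustworthy_sequence)
        assert len(records) == 250
        for r in records:
            assert 0.0 <= r.prior_trust <= 1.0
            assert 0.0 <= r.posterior_trust <= 1.0
            assert r.choice in (0, 1) and r.feedback in (0, 1)
            assert r.gamma_T > 0

    def test_run_is_reproducible(self, base_config, trustworthy_sequence):
        r1 = at.run_agent(base_config, trustworthy_sequence, n_trials=30)
        r2 = at.run_agent(base_config, trustworthy_sequence, n_trials=30)
        assert [x.choice for x in r1] == [x.choice for x in r2]
        assert [x.posterior_trust for x in r1] == [x.posterior_trust for x in r2]

    def test_alpha_invariance_under_action_replay(self, trustworthy_sequence):
        # with a fixed action sequence, alpha changes nothing about
        # inference: posteriors and gamma replay bit-identically
        cfg_lo = at.AgentConfig(choice_precision=0.5, seed=3)
        cfg_hi = at.AgentConfig(choice_precision=2.75, seed=3)
        replay = [(0, t % 2) for t in range(30)]
        r_lo = at.run_agent(cfg_lo, trustworthy_sequence, n_trials=30,
                            replay=replay)
        r_hi = at.run_agent(cfg_hi, trustworthy_sequence, n_trials=30,
                            replay=replay)
        assert [x.posterior_trust for x in r_lo] == \
            [x.posterior_trust for x in r_hi]
        assert [x.gamma_T for x in r_lo] == [x.gamma_T for x in r_hi]

    def test_single_policy_keeps_gamma_at_prior(self, base_config):
        # with one available policy pi == pi0 always, so beta never moves
        model = build_agent_model(base_config)
        engine_model = build_agent_model(base_config)
        engine_model.policies = [engine_model.policies[0]]
        engine_model.e = np.array([base_config.habit_resistance])
        from advisortask.inference_engine import TrialInference
        state = at.AgentState(model=engine_model,
                              engine=TrialInference(engine_model),
                              beta=engine_model.beta_prior,
                              beta_post=engine_model.beta_prior)
        rng = np.random.default_rng(0)
        seq = at.make_sequence("consistently_trustworthy", seed=0)
        from advisortask.inference_engine import TrialContext, run_trial
        for t in range(5):
            ctx = TrialContext(trial_index=t, true_intention=0,
                               correct_card=int(seq.correct_card[t]))
            run_trial(state, ctx, rng)
            assert state.beta_post == pytest.approx(engine_model.beta_prior)

    def test_treatment_formula(self):
        assert at.apply_treatment(0.25) == pytest.approx(0.25)
        assert at.apply_treatment(1.75) == pytest.approx(1.0)
        assert at.apply_treatment(1.0) == pytest.approx(0.625)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a=st.floats(0.55, 0.99), e0=st.floats(2.0, 600.0),
       seed=st.integers(0, 10_000))
def test_belief_vectors_normalized_across_configs(a, e0, seed):
    """Every per-policy state posterior is a probability vector at every
    timestep, whatever the parameters."""
    model = build_agent_model(at.AgentConfig(
        likelihood_precision=a, habit_resistance=e0, seed=seed))
    rng = np.random.default_rng(seed)
    advice = int(rng.integers(2))
    choice = int(rng.integers(2))
    feedback = int(rng.integers(2))
    obs = _observations(advice, choice, feedback)
    for policy in model.policies:
        post, F = at.infer_states(model, obs, policy)
        assert np.isfinite(F)
        for f, q in post.items():
            assert np.allclose(q.sum(axis=1), 1.0, atol=1e-8)
            assert (q >= -1e-12).all()


def test_records_roundtrip_to_csv(tmp_path, base_config, trustworthy_sequence):
    records = at.run_agent(base_config, trustworthy_sequence, n_trials=20)
    csv_path = tmp_path / "run.csv"
    sidecar = tmp_path / "run.json"
    at.save_run(records, base_config, csv_path, sidecar)
    import json
    import pandas as pd
    df = pd.read_csv(csv_path)
    assert len(df) == 20
    meta = json.loads(sidecar.read_text())
    assert meta["config"]["a"] == base_config.likelihood_precision
    assert len(meta["final_e"]) == 4
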