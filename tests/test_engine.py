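"""Active-inference engine: inference, free energies, action selection."""

import math

import numpy as np
import pytest

from protentia.categorical import (
    Categorical,
    FiniteSet,
    StochasticMap,
    ValidationError,
    entropy,
    kl_divergence,
    softmax,
)
from protentia.engine import (
    GenerativeModel,
    action_posterior,
    agent_step,
    exact_posterior,
    expected_free_energy,
    free_energy,
    from_stoch_poly,
    rollout_policies,
    to_stoch_poly,
)
from protentia.fixtures import dirichlet_like, random_model
from protentia.poly import run_system


def random_belief(model, rng):
    return Categorical(model.states, dirichlet_like(rng, len(model.states)))


class TestExactPosterior:
    def test_noiseless_likelihood_collapses(self, identity_model):
        post = exact_posterior(identity_model, identity_model.D, "o1")
        assert np.allclose(post.probs, [1.0, 0.0])

    def test_uninformative_likelihood_returns_prior(self):
        S = FiniteSet(["s1", "s2"])
        O = FiniteSet(["o1", "o2"])
        U = FiniteSet(["u1"])
        m = GenerativeModel(states=S, observations=O, actions=U,
                            A=StochasticMap(S, O, [[0.5, 0.5], [0.5, 0.5]]),
                            B={"u1": StochasticMap.identity(S)},
                            C=Categorical.uniform(O), D=Categorical(S, [0.3, 0.7]),
                            E=Categorical.uniform(U))
        post = exact_posterior(m, m.D, "o1")
        assert np.allclose(post.probs, [0.3, 0.7])

    def test_hand_bayes(self, two_state_model):
        post = exact_posterior(two_state_model, two_state_model.D, "o1")
        assert np.allclose(post.probs, [9 / 11, 2 / 11])

    def test_impossible_observation_rejected(self, identity_model):
        prior = Categorical(identity_model.states, [1.0, 0.0])
        with pytest.raises(ValidationError, match="impossible"):
            exact_posterior(identity_model, prior, "o2")


class TestFreeEnergy:
    def test_at_posterior_divergence_vanishes_and_F_is_neg_log_evidence(self, two_state_model):
        m = two_state_model
        post = exact_posterior(m, m.D, "o1")
        fe = free_energy(m, post, m.D, "o1")
        evidence = 0.5 * 0.9 + 0.5 * 0.2
        assert fe.divergence == pytest.approx(0.0, abs=1e-12)
        assert fe.F == pytest.approx(-math.log(evidence), abs=1e-10)

    def test_noiseless_example_gives_ln2(self, identity_model):
        q = Categorical(identity_model.states, [1.0, 0.0])
        fe = free_energy(identity_model, q, identity_model.D, "o1")
        assert fe.F == pytest.approx(math.log(2), abs=1e-12)

    def test_decompositions_agree_on_random_triples(self):
        for seed in range(200):
            m = random_model(4, 3, 2, seed=seed)
            rng = np.random.default_rng(10_000 + seed)
            q = random_belief(m, rng)
            o = m.observations.labels[seed % 3]
            fe = free_energy(m, q, m.D, o)
            assert abs(fe.F - (fe.divergence - fe.log_evidence)) < 1e-9
            assert abs(fe.F - (fe.complexity - fe.accuracy)) < 1e-9

    def test_evidence_bound_strict_off_posterior(self):
        for seed in range(50):
            m = random_model(3, 3, 2, seed=seed)
            rng = np.random.default_rng(seed)
            q = random_belief(m, rng)
            o = "o0"
            post = exact_posterior(m, m.D, o)
            f_q = free_energy(m, q, m.D, o).F
            f_post = free_energy(m, post, m.D, o).F
            assert f_q >= f_post - 1e-12
            if kl_divergence(q, post) > 1e-8:
                assert f_q > f_post


class TestExpectedFreeEnergy:
    def test_deterministic_likelihood_has_zero_ambiguity(self, identity_model):
        g = expected_free_energy(identity_model, identity_model.D)
        assert g.ambiguity == pytest.approx(0.0, abs=1e-15)

    def test_matching_preferences_give_zero_risk(self):
        S = FiniteSet(["s1", "s2"])
        O = FiniteSet(["o1", "o2"])
        U = FiniteSet(["u1"])
        A = StochasticMap(S, O, [[0.7, 0.7], [0.3, 0.3]])
        m = GenerativeModel(states=S, observations=O, actions=U, A=A,
                            B={"u1": StochasticMap.identity(S)},
                            C=Categorical(O, [0.7, 0.3]),
                            D=Categorical.uniform(S), E=Categorical.uniform(U))
        g = expected_free_energy(m, m.D)
        assert g.risk == pytest.approx(0.0, abs=1e-12)

    def test_direct_summation_oracle_on_two_state_model(self, two_state_model):
        """Brute-force sums over all four (s, o) outcomes reproduce the report."""
        m = two_state_model
        q_next = Categorical(m.states, [0.5, 0.5])
        rep = expected_free_energy(m, q_next)
        A = m.A.table
        q_o = A @ q_next.probs
        risk = sum(q_o[i] * math.log(q_o[i] / m.C.probs[i]) for i in range(2))
        ambiguity = sum(q_next.probs[j] * entropy(A[:, j]) for j in range(2))
        assert rep.risk == pytest.approx(risk, abs=1e-12)
        assert rep.ambiguity == pytest.approx(ambiguity, abs=1e-12)
        assert rep.G == pytest.approx(risk + ambiguity, abs=1e-12)

    def test_decompositions_agree_on_random_models(self):
        for seed in range(200):
            m = random_model(3, 4, 2, seed=seed)
            rng = np.random.default_rng(20_000 + seed)
            q = m.predict(random_belief(m, rng), "u0")
            g = expected_free_energy(m, q)
            assert abs(g.G - (g.risk + g.ambiguity)) < 1e-9
            assert abs(g.G - (-g.info_gain - g.expected_value)) < 1e-9

    def test_zero_preference_mass_flags_infinite_risk(self, two_state_model):
        m = two_state_model
        m2 = GenerativeModel(states=m.states, observations=m.observations,
                             actions=m.actions, A=m.A, B=m.B,
                             C=Categorical(m.observations, [1.0, 0.0]),
                             D=m.D, E=m.E, gamma=m.gamma)
        g = expected_free_energy(m2, m2.D)
        assert g.risk_is_infinite and g.G == math.inf


class TestActionPosterior:
    def test_zero_precision_is_uniform(self, two_state_model):
        m = two_state_model
        m0 = GenerativeModel(states=m.states, observations=m.observations,
                             actions=m.actions, A=m.A, B=m.B, C=m.C, D=m.D,
                             E=m.E, gamma=0.0)
        assert np.allclose(action_posterior(m0, [3.0, -1.0]).probs, [0.5, 0.5])

    def test_closed_form(self, two_state_model):
        p = action_posterior(two_state_model, [0.0, math.log(2)])
        assert np.allclose(p.probs, [2 / 3, 1 / 3], atol=1e-12)

    def test_hard_habit_dominates(self, two_state_model):
        m = two_state_model
        mh = GenerativeModel(states=m.states, observations=m.observations,
                             actions=m.actions, A=m.A, B=m.B, C=m.C, D=m.D,
                             E=Categorical(m.actions, [1.0, 0.0]), gamma=1.0)
        assert np.array_equal(action_posterior(mh, [100.0, -100.0]).probs, [1.0, 0.0])

    def test_uniform_habit_reduces_to_plain_softmax(self, two_state_model):
        g = [0.3, 1.7]
        assert np.allclose(action_posterior(two_state_model, g).probs,
                           softmax(g, two_state_model.gamma).probs, atol=1e-15)

    def test_monotone_in_single_g(self, two_state_model):
        p1 = action_posterior(two_state_model, [1.0, 1.0])["u1"]
        p2 = action_posterior(two_state_model, [1.5, 1.0])["u1"]
        assert p2 < p1


class TestRolloutPolicies:
    def test_depth_one_matches_per_action_efe(self, two_state_model):
        m = two_state_model
        res = dict((pol.actions, g) for pol, g in rollout_policies(m, m.D, depth=1))
        for u in m.actions:
            g = expected_free_energy(m, m.predict(m.D, u)).G
            assert res[(u,)] == pytest.approx(g, abs=1e-12)

    def test_symmetric_model_ties_all_policies(self):
        S = FiniteSet(["s1", "s2"])
        O = FiniteSet(["o1", "o2"])
        U = FiniteSet(["u1", "u2"])
        # both actions act identically: every policy must tie
        B = {u: StochasticMap(S, S, [[0.5, 0.5], [0.5, 0.5]]) for u in U}
        m = GenerativeModel(states=S, observations=O, actions=U,
                            A=StochasticMap(S, O, [[0.8, 0.2], [0.2, 0.8]]), B=B,
                            C=Categorical.uniform(O), D=Categorical.uniform(S),
                            E=Categorical.uniform(U))
        gs = [g for _, g in rollout_policies(m, m.D, depth=2)]
        assert np.allclose(gs, gs[0], atol=1e-12)

    def test_cap_enforced(self, two_state_model):
        with pytest.raises(ValidationError, match="cap"):
            rollout_policies(two_state_model, two_state_model.D, depth=3, cap=7)

    def test_habit_prior_weight_is_product(self, two_state_model):
        for pol, _ in rollout_policies(two_state_model, two_state_model.D, depth=2):
            expected = np.prod([two_state_model.E[u] for u in pol.actions])
            assert pol.prior_weight == pytest.approx(expected)


class TestAgentStep:
    def test_high_precision_is_greedy(self, two_state_model, rng):
        m = two_state_model
        mg = GenerativeModel(states=m.states, observations=m.observations,
                             actions=m.actions, A=m.A, B=m.B, C=m.C, D=m.D,
                             E=m.E, gamma=1e6)
        res = agent_step(mg, mg.D, "o1", rng)
        gs = {u: r.G for u, r in res.efe.items()}
        assert res.action == min(sorted(gs), key=lambda u: gs[u])

    def test_repeated_observation_leaves_collapsed_belief(self, identity_model, rng):
        m = identity_model
        r1 = agent_step(m, m.D, "o1", rng)
        r2 = agent_step(m, r1.next_prior, "o1", rng)
        assert np.allclose(r1.posterior.probs, r2.posterior.probs, atol=1e-12)

    def test_fifty_step_invariant_sweep(self):
        m = random_model(3, 3, 2, seed=5)
        rng = np.random.default_rng(5)
        belief = m.D
        for _ in range(50):
            o = m.observations.labels[rng.integers(3)]
            res = agent_step(m, belief, o, rng)
            assert abs(res.posterior.probs.sum() - 1.0) < 1e-9
            assert np.isfinite(res.free_energy.F)
            belief = res.next_prior


class TestStochPolyBridge:
    def test_round_trip_reproduces_tables(self, two_state_model):
        sys = to_stoch_poly(two_state_model)
        A, B = from_stoch_poly(sys)
        assert np.array_equal(A.table, two_state_model.A.table)
        for u in two_state_model.actions:
            assert np.array_equal(B[u].table, two_state_model.B[u].table)

    def test_interface_is_observation_action_monomial(self, two_state_model):
        sys = to_stoch_poly(two_state_model)
        assert sys.interface.positions.labels == two_state_model.observations.labels
        for o in sys.interface.positions:
            assert sys.interface.directions[o].labels == two_state_model.actions.labels

    def test_deterministic_output_mode_requires_noiseless_likelihood(self, two_state_model,
                                                                     identity_model):
        with pytest.raises(ValidationError):
            to_stoch_poly(two_state_model, deterministic_output=True)
        sys = to_stoch_poly(identity_model, deterministic_output=True)
        rng = np.random.default_rng(0)
        assert sys.output("s2", rng) == "o2"

    def test_trajectory_bit_identical_to_direct_simulation(self):
        m = random_model(3, 3, 2, seed=9)
        inputs = [m.actions.labels[i % 2] for i in range(40)]
        sys = to_stoch_poly(m)
        traj = run_system(sys, inputs, "s0", np.random.default_rng(77))

        # independent simulation loop with the same draw discipline
        rng = np.random.default_rng(77)
        s, direct = "s0", []
        for u in inputs:
            o = m.A.column(s).sample(rng)
            direct.append((s, o))
            s = m.B[u].column(s).sample(rng)
        direct.append((s, m.A.column(s).sample(rng)))
        assert traj == direct
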