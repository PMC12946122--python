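"""Discrete POMDP: belief filtering, costs, and the brute-force planner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronodyn.pomdp import (
    Belief,
    DiscretePOMDP,
    History,
    ImpossibleObservationError,
    belief_update,
    brute_force_policy,
    enumerate_path_posterior,
    expected_policy_cost,
    filter_history,
    trajectory_cost,
)
from chronodyn.synth import generate_discrete_pomdp


def _random_model(rng, n_states, n_obs, n_actions, gamma=0.9):
    return DiscretePOMDP(
        trans=rng.dirichlet(np.ones(n_states), size=(n_states, n_actions)),
        obs_lik=rng.dirichlet(np.ones(n_obs), size=n_states),
        cost=rng.uniform(0, 1, size=(n_states, n_actions)),
        gamma=gamma,
    )


class TestBeliefUpdate:
    def test_deterministic_identity_gives_one_hot(self):
        # deterministic cycle transitions, each state emits its own symbol
        trans = np.zeros((3, 1, 3))
        for s in range(3):
            trans[s, 0, (s + 1) % 3] = 1.0
        model = DiscretePOMDP(trans=trans, obs_lik=np.eye(3),
                              cost=np.zeros((3, 1)), gamma=0.5)
        out = belief_update(Belief.uniform(3), 0, 2, model)
        assert np.allclose(out.probs, [0.0, 0.0, 1.0])

    def test_uniform_stays_uniform_under_symmetry(self):
        n = 4
        model = DiscretePOMDP(
            trans=np.full((n, 2, n), 1.0 / n),
            obs_lik=np.full((n, 3), 1.0 / 3),
            cost=np.zeros((n, 2)),
            gamma=0.0,
        )
        out = belief_update(Belief.uniform(n), 1, 0, model)
        assert np.allclose(out.probs, 1.0 / n)

    def test_hand_enumeration_example(self, two_state_model, uniform2):
        out = belief_update(uniform2, 0, 0, two_state_model)
        # predicted = [0.55, 0.45]; corrected by [0.7, 0.3] and normalized
        assert np.allclose(out.probs, [0.74038461538, 0.25961538461], atol=1e-10)

    def test_impossible_observation_raises_with_pair(self):
        model = DiscretePOMDP(
            trans=np.array([[[1.0, 0.0]], [[1.0, 0.0]]]),
            obs_lik=np.array([[1.0, 0.0], [0.0, 1.0]]),
            cost=np.zeros((2, 1)),
            gamma=0.0,
        )
        # after the transition all mass is on state 0, which never emits symbol 1
        with pytest.raises(ImpossibleObservationError, match="observation 1.*action 0"):
            belief_update(Belief(np.array([0.3, 0.7])), 0, 1, model)


class TestFilterHistory:
    def test_single_observation_identity_emission(self):
        model = DiscretePOMDP(
            trans=np.full((3, 1, 3), 1.0 / 3), obs_lik=np.eye(3),
            cost=np.zeros((3, 1)), gamma=0.0,
        )
        beliefs = filter_history(History(actions=(), observations=(1,)), model)
        assert len(beliefs) == 1
        assert np.allclose(beliefs[0].probs, [0, 1, 0])

    def test_one_state_model_degenerate(self):
        model = DiscretePOMDP(
            trans=np.ones((1, 2, 1)), obs_lik=np.ones((1, 1)),
            cost=np.zeros((1, 2)), gamma=0.0,
        )
        hist = History(actions=(0, 1, 0), observations=(0, 0, 0, 0))
        beliefs = filter_history(hist, model)
        assert all(np.allclose(b.probs, [1.0]) for b in beliefs)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_path_enumeration(self, seed):
        """Recursive filtering equals the posterior from summing all latent paths."""
        rng = np.random.default_rng(seed)
        model = _random_model(rng, 3, 3, 2)
        T = 5
        hist = History(
            actions=rng.integers(0, 2, T - 1), observations=rng.integers(0, 3, T)
        )
        beliefs = filter_history(hist, model)
        oracle = enumerate_path_posterior(hist, model)
        for t, b in enumerate(beliefs):
            assert np.max(np.abs(b.probs - oracle[t])) < 1e-10

    def test_belief_normalization_after_long_chain(self):
        rng = np.random.default_rng(42)
        model = _random_model(rng, 4, 4, 3)
        hist = History(
            actions=rng.integers(0, 3, 30), observations=rng.integers(0, 4, 31)
        )
        for b in filter_history(hist, model):
            assert abs(b.probs.sum() - 1.0) <= 1e-12

    def test_state_relabeling_invariance(self):
        """Permuting state labels consistently permutes beliefs and preserves costs."""
        rng = np.random.default_rng(7)
        model = _random_model(rng, 4, 3, 2)
        perm = np.array([2, 0, 3, 1])
        model_p = DiscretePOMDP(
            trans=model.trans[perm][:, :, perm],
            obs_lik=model.obs_lik[perm],
            cost=model.cost[perm],
            gamma=model.gamma,
        )
        hist = History(actions=rng.integers(0, 2, 5), observations=rng.integers(0, 3, 6))
        b1 = filter_history(hist, model)
        b2 = filter_history(hist, model_p)
        for x, y in zip(b1, b2):
            assert np.allclose(x.probs[perm], y.probs, atol=1e-12)
        states = rng.integers(0, 4, 5)
        actions = rng.integers(0, 2, 5)
        inv = np.argsort(perm)
        assert trajectory_cost(states, actions, model) == pytest.approx(
            trajectory_cost(inv[states], actions, model_p)
        )


class TestTrajectoryCost:
    def test_gamma_zero_keeps_only_first_term(self, two_state_model):
        model = DiscretePOMDP(
            trans=two_state_model.trans, obs_lik=two_state_model.obs_lik,
            cost=two_state_model.cost, gamma=0.0,
        )
        assert trajectory_cost([1, 0, 1], [0, 0, 0], model) == pytest.approx(3.0)

    def test_geometric_sum_of_unit_costs(self):
        model = DiscretePOMDP(
            trans=np.ones((1, 1, 1)), obs_lik=np.ones((1, 1)),
            cost=np.ones((1, 1)), gamma=0.5,
        )
        assert trajectory_cost([0, 0, 0], [0, 0, 0], model) == pytest.approx(1.75)

    def test_hand_evaluated_two_steps(self):
        model = DiscretePOMDP(
            trans=np.full((2, 2, 2), 0.5), obs_lik=np.ones((2, 1)),
            cost=np.array([[1.0, 2.0], [3.0, 4.0]]), gamma=0.9,
        )
        assert trajectory_cost([0, 1], [1, 0], model) == pytest.approx(4.7)

    def test_length_mismatch_raises(self, two_state_model):
        with pytest.raises(ValueError, match="mismatch"):
            trajectory_cost([0, 1], [0], two_state_model)

    @given(g1=st.floats(0, 0.98), g2=st.floats(0, 0.98))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_discount(self, g1, g2):
        """With nonnegative costs, a larger discount never lowers the total."""
        lo, hi = sorted([g1, g2])
        rng = np.random.default_rng(0)
        cost = rng.uniform(0, 1, size=(3, 2))
        trans = np.full((3, 2, 3), 1.0 / 3)
        obs = np.ones((3, 1))
        m_lo = DiscretePOMDP(trans=trans, obs_lik=obs, cost=cost, gamma=lo)
        m_hi = DiscretePOMDP(trans=trans, obs_lik=obs, cost=cost, gamma=hi)
        states, actions = [0, 2, 1, 0], [1, 0, 1, 1]
        assert trajectory_cost(states, actions, m_hi) >= trajectory_cost(
            states, actions, m_lo) - 1e-12


class TestExpectedPolicyCost:
    def test_zero_costs_give_zero(self):
        model = DiscretePOMDP(
            trans=np.eye(2)[:, None, :], obs_lik=np.ones((2, 1)),
            cost=np.zeros((2, 1)), gamma=0.9,
        )
        assert expected_policy_cost([0, 0, 0], model, 3, Belief.uniform(2)) == 0.0

    def test_one_state_closed_form(self):
        c, gamma, T = 2.5, 0.8, 6
        model = DiscretePOMDP(
            trans=np.ones((1, 1, 1)), obs_lik=np.ones((1, 1)),
            cost=np.array([[c]]), gamma=gamma,
        )
        expected = c * (1 - gamma**T) / (1 - gamma)
        assert expected_policy_cost([0] * T, model, T, Belief([1.0])) == pytest.approx(expected)

    def test_matches_monte_carlo_for_belief_policy(self):
        """Exact observation-branch expectation agrees with 1e5-rollout simulation."""
        model = generate_discrete_pomdp(2, 2, 2, gamma=0.8, seed=11)
        init = Belief(np.array([0.6, 0.4]))

        def policy(b, t):
            return int(b.probs[1] > 0.5)

        exact = expected_policy_cost(policy, model, 4, init)
        rng = np.random.default_rng(0)
        N = 100_000
        costs = np.zeros(N)
        for i in range(N):
            s = rng.choice(2, p=init.probs)
            b = init
            disc = 1.0
            for t in range(4):
                a = policy(b, t)
                costs[i] += disc * model.cost[s, a]
                s = rng.choice(2, p=model.trans[s, a])
                if t < 3:
                    x = rng.choice(2, p=model.obs_lik[s])
                    b = belief_update(b, a, x, model)
                disc *= model.gamma
        se = costs.std() / np.sqrt(N)
        assert abs(exact - costs.mean()) < 3 * se


class TestBruteForcePolicy:
    def test_dominant_action_repeated(self):
        trans = np.stack([np.full((2, 2), 0.5)] * 2, axis=1)  # identical dynamics
        model = DiscretePOMDP(
            trans=trans, obs_lik=np.ones((2, 1)),
            cost=np.array([[1.0, 0.2], [1.0, 0.2]]), gamma=0.9,
        )
        seq, _ = brute_force_policy(model, 3, Belief.uniform(2))
        assert seq == (1, 1, 1)

    def test_horizon_one_is_myopic(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng, 3, 2, 4)
        b = Belief(rng.dirichlet(np.ones(3)))
        seq, cost = brute_force_policy(model, 1, b)
        myopic = np.argmin(b.probs @ model.cost)
        assert seq == (int(myopic),)
        assert cost == pytest.approx(float((b.probs @ model.cost).min()))

    def test_matches_explicit_enumeration(self):
        rng = np.random.default_rng(9)
        model = _random_model(rng, 2, 2, 2)
        b = Belief(np.array([0.5, 0.5]))
        seq, cost = brute_force_policy(model, 3, b)
        best = min(
            ((a0, a1, a2) for a0 in range(2) for a1 in range(2) for a2 in range(2)),
            key=lambda s: (expected_policy_cost(list(s), model, 3, b), s),
        )
        assert seq == best
        assert cost == pytest.approx(expected_policy_cost(list(best), model, 3, b))

    def test_enumeration_cap(self):
        rng = np.random.default_rng(1)
        model = _random_model(rng, 2, 2, 3)
        with pytest.raises(ValueError, match="cap"):
            brute_force_policy(model, 20, Belief.uniform(2), enumeration_cap=100)


class TestSerialization:
    def test_json_round_trip_bit_stable(self, two_state_model, tmp_path):
        path = tmp_path / "model.json"
        two_state_model.to_json(path)
        back = DiscretePOMDP.from_json(path)
        assert np.array_equal(back.trans, two_state_model.trans)
        assert np.array_equal(back.obs_lik, two_state_model.obs_lik)
        assert np.array_equal(back.cost, two_state_model.cost)
        assert back.gamma == two_state_model.gamma


class TestValidation:
    def test_rejects_unnormalized_transitions(self):
        with pytest.raises(ValueError, match="probability"):
            DiscretePOMDP(
                trans=np.array([[[0.5, 0.4]], [[0.5, 0.5]]]),
                obs_lik=np.ones((2, 1)), cost=np.zeros((2, 1)), gamma=0.5,
            )

    def test_rejects_gamma_one(self):
        with pytest.raises(ValueError, match="gamma"):
            DiscretePOMDP(
                trans=np.ones((1, 1, 1)), obs_lik=np.ones((1, 1)),
                cost=np.zeros((1, 1)), gamma=1.0,
            )

    def test_history_length_contract(self):
        with pytest.raises(ValueError, match="observations"):
            History(actions=(0, 1), observations=(0, 1))
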