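"""Policy rollouts, mismatch objectives, gradients, and trust-region recalibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronodyn.dynamics import ConditionLayout
from chronodyn.policy import (
    CostModel,
    PolicyNet,
    RecalibrationConfig,
    alignment_objective,
    brute_force_window,
    condition_mismatch,
    cumulative_alignment,
    expected_step_cost,
    kl_divergence,
    policy_action,
    policy_gradient_step,
    recalibrate_window,
    rollout,
    total_objective,
    trajectory_mismatch,
    window_loss,
    window_loss_and_grad,
)


def _clipped_tensor(rng, d, m, bound=0.95):
    T_p = rng.normal(size=(d, d, m))
    for a in range(m):
        n = np.linalg.norm(T_p[:, :, a], ord=2)
        if n > bound:
            T_p[:, :, a] *= bound / n
    return T_p


class TestRollout:
    def test_zero_horizon_returns_start(self):
        pol = PolicyNet.init(2, 2, seed=0)
        s = np.array([0.1, -0.2])
        path = rollout(s, pol, np.zeros((2, 2, 2)), "tanh", 0)
        assert path.shape == (1, 2)
        assert np.array_equal(path[0], s)

    def test_identity_dynamics_constant_path(self):
        T_p = np.stack([np.eye(2)] * 3, axis=2)
        pol = PolicyNet.init(2, 3, seed=1)
        s = np.array([0.4, 0.2])
        path = rollout(s, pol, T_p, "identity", 4, mode="argmax")
        assert np.allclose(path, np.tile(s, (5, 1)))

    def test_two_step_hand_simulation(self):
        """Hand-check: a policy that always picks action 0 on a 2-d system."""
        T_p = np.zeros((2, 2, 2))
        T_p[:, :, 0] = [[0.0, 0.5], [0.5, 0.0]]
        T_p[:, :, 1] = np.eye(2)
        # logits fixed at [5, 0] -> argmax = action 0
        pol = PolicyNet(W1=np.zeros((2, 2)), b1=np.zeros(2),
                        W2=np.zeros((2, 2)), b2=np.array([5.0, 0.0]))
        s0 = np.array([0.8, -0.4])
        path = rollout(s0, pol, T_p, "tanh", 2, mode="argmax")
        s1 = np.tanh(T_p[:, :, 0] @ s0)
        s2 = np.tanh(T_p[:, :, 0] @ s1)
        assert np.allclose(path, np.stack([s0, s1, s2]), atol=1e-12)

    def test_sample_mode_seeded(self):
        rng = np.random.default_rng(0)
        T_p = _clipped_tensor(rng, 3, 2)
        pol = PolicyNet.init(3, 2, seed=3)
        s = rng.normal(size=3)
        a = rollout(s, pol, T_p, "tanh", 5, mode="sample", seed=42)
        b = rollout(s, pol, T_p, "tanh", 5, mode="sample", seed=42)
        assert np.array_equal(a, b)


class TestMismatch:
    def test_identical_paths_zero(self):
        p = np.random.default_rng(0).normal(size=(4, 3))
        assert trajectory_mismatch(p, p) == 0.0

    def test_unit_vectors_sum_to_length(self):
        H = 3
        inferred = np.eye(3)[:1].repeat(H + 1, axis=0)
        assert trajectory_mismatch(np.zeros((H + 1, 3)), inferred) == pytest.approx(H + 1)

    def test_single_block_equals_total(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        cm = condition_mismatch(a, b, ConditionLayout((4,)))
        assert cm.shape == (1,)
        assert cm[0] == pytest.approx(trajectory_mismatch(a, b))

    def test_identical_block_contributes_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 5))
        b = a.copy()
        b[:, 2:] = rng.normal(size=(4, 3))
        cm = condition_mismatch(a, b, ConditionLayout((2, 3)))
        assert cm[0] == 0.0 and cm[1] > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_blocks_sum_to_total(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        cm = condition_mismatch(a, b, ConditionLayout((2, 3)))
        assert abs(cm.sum() - trajectory_mismatch(a, b)) < 1e-12


class TestObjectives:
    def test_alignment_reduces_to_delta(self):
        assert alignment_objective([2.5], [1.0], [9.0], 0.0) == pytest.approx(2.5)

    def test_cost_term_arithmetic(self):
        assert alignment_objective([0.0], [1.0], [1.0, 2.0], 2.0) == pytest.approx(6.0)

    def test_weight_linearity(self):
        deltas, w = [1.0, 2.0], [0.5, 1.5]
        base = alignment_objective(deltas, w, [], 0.0)
        assert alignment_objective(deltas, [2 * x for x in w], [], 0.0) == pytest.approx(2 * base)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            alignment_objective([1.0], [-1.0], [], 0.0)

    def test_total_objective_forms(self):
        pol = PolicyNet.init(2, 2, seed=0)
        other = PolicyNet.init(2, 2, seed=1)
        states = np.zeros((1, 2))
        assert total_objective(1.5, pol, other, states, 0.0) == pytest.approx(1.5)
        assert total_objective(1.5, pol, pol, states, 7.0) == pytest.approx(1.5)

    def test_total_objective_hand_value(self):
        # distributions [1,0] vs [0.5,0.5] at one eval state: KL = ln 2
        big = PolicyNet(W1=np.zeros((2, 2)), b1=np.zeros(2),
                        W2=np.zeros((2, 2)), b2=np.array([40.0, 0.0]))
        unif = PolicyNet(W1=np.zeros((2, 2)), b1=np.zeros(2),
                         W2=np.zeros((2, 2)), b2=np.zeros(2))
        val = total_objective(1.0, big, unif, np.zeros((1, 2)), 2.0)
        assert val == pytest.approx(1.0 + 2 * np.log(2), abs=1e-6)

    def test_expected_step_cost_cases(self):
        cm = CostModel(np.zeros((2, 2)), np.array([0.0, 2.0]))
        assert expected_step_cost(np.zeros(2), [0.5, 0.5], cm) == pytest.approx(1.0)
        cm0 = CostModel(np.eye(2), np.array([0.0, 5.0]))
        assert expected_step_cost(np.zeros(2), [1.0, 0.0], cm0) == pytest.approx(0.0)
        assert expected_step_cost(np.array([1.0, 1.0]), [0.0, 1.0], cm0) == pytest.approx(7.0)

    def test_cumulative_alignment(self):
        assert cumulative_alignment([]) == 0.0
        assert cumulative_alignment([4.2]) == pytest.approx(4.2)
        assert cumulative_alignment([1.0, 2.0, 3.0]) == pytest.approx(6.0)


class TestPolicyAction:
    def test_zero_weights_uniform(self):
        pol = PolicyNet(W1=np.zeros((3, 2)), b1=np.zeros(3),
                        W2=np.zeros((4, 3)), b2=np.zeros(4))
        assert np.allclose(policy_action(np.ones(2), pol), 0.25)

    def test_logit_shift_invariance(self):
        pol = PolicyNet(W1=np.zeros((2, 2)), b1=np.zeros(2),
                        W2=np.zeros((2, 2)), b2=np.array([1.0, 3.0]))
        shifted = PolicyNet(W1=pol.W1, b1=pol.b1, W2=pol.W2,
                            b2=pol.b2 + 10.0)
        s = np.zeros(2)
        assert np.allclose(policy_action(s, pol), policy_action(s, shifted))

    def test_hand_softmax(self):
        pol = PolicyNet(W1=np.zeros((2, 2)), b1=np.zeros(2),
                        W2=np.zeros((2, 2)), b2=np.array([np.log(2.0), 0.0]))
        assert np.allclose(policy_action(np.zeros(2), pol), [2 / 3, 1 / 3])


class TestKL:
    def test_identical_zero(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0)

    def test_hand_value_ln2(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_infinite_when_support_lost(self):
        assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == np.inf

    @given(st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gibbs_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        p, q = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
        assert kl_divergence(p, q) >= 0.0

    def test_asymmetry_witness(self):
        p, q = np.array([0.9, 0.1]), np.array([0.5, 0.5])
        assert kl_divergence(p, q) != pytest.approx(kl_divergence(q, p))


class TestGradients:
    def test_eta_zero_no_change(self):
        pol = PolicyNet.init(2, 2, seed=0)
        out = policy_gradient_step(pol, lambda p: 1.0, 0.0)
        assert out is pol

    def test_hand_quadratic_step(self):
        """Loss (w-3)^2 in a single parameter: one step from 0 with eta=0.1 gives 0.6."""
        pol = PolicyNet(W1=np.zeros((1, 1)), b1=np.zeros(1),
                        W2=np.zeros((1, 1)), b2=np.zeros(1))

        def loss(p):
            return float((p.b2[0] - 3.0) ** 2)

        out = policy_gradient_step(pol, loss, 0.1)
        assert out.b2[0] == pytest.approx(0.6, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_analytic_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        d, m, H = 3, 3, 3
        T_p = _clipped_tensor(rng, d, m)
        pol = PolicyNet.init(d, m, hidden_dim=5, seed=seed + 100)
        pol_old = PolicyNet.init(d, m, hidden_dim=5, seed=seed + 200)
        cost = CostModel(np.eye(d), rng.uniform(0, 1, m))
        cfg = RecalibrationConfig(horizon=H, lam=0.6, beta=0.4, eta=0.1, iters=1)
        inferred = rng.normal(size=(H + 1, d)) * 0.5
        _, g = window_loss_and_grad(pol, inferred[0], inferred, T_p, cost, cfg, pol_old)
        flat = pol.flatten()
        fd = np.empty_like(flat)
        eps = 1e-6
        for i in range(len(flat)):
            up, dn = flat.copy(), flat.copy()
            up[i] += eps
            dn[i] -= eps
            fd[i] = (
                window_loss(pol.with_flat(up), inferred[0], inferred, T_p, cost, cfg, pol_old)
                - window_loss(pol.with_flat(dn), inferred[0], inferred, T_p, cost, cfg, pol_old)
            ) / (2 * eps)
        rel = np.linalg.norm(g - fd) / max(np.linalg.norm(fd), 1e-12)
        assert rel < 1e-4


class TestRecalibration:
    def test_already_aligned_stays_put(self):
        """If the inferred path is the policy's own rollout, Δ starts at 0 and stays small."""
        rng = np.random.default_rng(0)
        d, m, H = 3, 2, 3
        T_p = _clipped_tensor(rng, d, m)
        pol = PolicyNet.init(d, m, seed=1)
        inferred = rollout(rng.normal(size=d) * 0.5, pol, T_p, "tanh", H, mode="soft")
        cfg = RecalibrationConfig(horizon=H, beta=1.0, eta=0.1, iters=20)
        rep = recalibrate_window(inferred[0], inferred, pol, T_p,
                                 CostModel.zero(d, m), cfg)
        assert rep.delta_trace[0] == pytest.approx(0.0, abs=1e-12)
        assert rep.delta_trace[-1] <= 1e-8
        assert np.all(rep.kl_trace <= rep.objective_trace[0] / cfg.beta + 1e-12)

    def test_achievable_target_reached(self):
        """Target path generated by a known action sequence is recovered to Δ ≈ 0."""
        rng = np.random.default_rng(3)
        d, m, H = 3, 3, 3
        T_p = _clipped_tensor(rng, d, m)
        s0 = rng.normal(size=d) * 0.8
        seq = rng.integers(0, m, size=H)
        s, target = s0, [s0]
        for a in seq:
            s = np.tanh(T_p[:, :, a] @ s)
            target.append(s)
        target = np.stack(target)
        pol = PolicyNet.uniform_init(d, m, seed=3)
        cfg = RecalibrationConfig(horizon=H, eta=0.5, iters=200)
        rep = recalibrate_window(s0, target, pol, T_p, CostModel.zero(d, m), cfg,
                                 mode="hard")
        _, bf = brute_force_window(s0, target, T_p, "tanh", H)
        assert bf == pytest.approx(0.0, abs=1e-12)
        assert rep.delta_trace[-1] <= 0.1 * rep.delta_trace[0]
        assert rep.delta_trace[-1] >= bf - 1e-12

    def test_huge_beta_freezes_policy(self):
        rng = np.random.default_rng(5)
        d, m, H = 3, 2, 3
        T_p = _clipped_tensor(rng, d, m)
        pol = PolicyNet.init(d, m, seed=2)
        target = rng.normal(size=(H + 1, d)) * 0.5
        cfg = RecalibrationConfig(horizon=H, beta=1e6, eta=0.5, iters=30)
        rep = recalibrate_window(target[0], target, pol, T_p, CostModel.zero(d, m), cfg)
        assert rep.kl_trace[-1] <= 1e-3

    def test_final_kl_monotone_in_beta(self):
        rng = np.random.default_rng(7)
        d, m, H = 3, 3, 3
        T_p = _clipped_tensor(rng, d, m)
        target = rng.normal(size=(H + 1, d)) * 0.5
        kls = []
        for beta in (0.0, 1.0, 100.0):
            pol = PolicyNet.init(d, m, seed=4)
            cfg = RecalibrationConfig(horizon=H, beta=beta, eta=0.5, iters=40)
            rep = recalibrate_window(target[0], target, pol, T_p,
                                     CostModel.zero(d, m), cfg)
            kls.append(rep.kl_trace[-1])
        assert kls[0] >= kls[1] >= kls[2]

    def test_objective_trace_nonincreasing(self):
        rng = np.random.default_rng(9)
        d, m, H = 2, 2, 2
        T_p = _clipped_tensor(rng, d, m)
        pol = PolicyNet.init(d, m, seed=0)
        target = rng.normal(size=(H + 1, d))
        cfg = RecalibrationConfig(horizon=H, lam=0.3, eta=0.2, iters=25)
        rep = recalibrate_window(target[0], target, pol, T_p,
                                 CostModel(np.eye(d), np.ones(m)), cfg)
        assert np.all(np.diff(rep.objective_trace) <= 1e-12)

    def test_wrong_window_length_rejected(self):
        pol = PolicyNet.init(2, 2, seed=0)
        cfg = RecalibrationConfig(horizon=3)
        with pytest.raises(ValueError, match="H\\+1"):
            recalibrate_window(np.zeros(2), np.zeros((2, 2)), pol,
                               np.zeros((2, 2, 2)), CostModel.zero(2, 2), cfg)
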