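"""Trajectory-aligned recalibration of treatment policies.

At each planning window the current softmax policy is rolled forward
through the patient's latent dynamics, the predicted path is compared with
the path retrospectively inferred from the observations that actually
arrived, and the policy parameters are nudged by gradient descent to shrink
the mismatch — subject to an intervention-cost term and a KL trust region
that keeps each update close to the previous policy.

The objective is minimized (mismatch + λ·cost + β·KL); the gradient is
computed by exact reverse-mode differentiation through the *soft* rollout,
in which each step uses the policy-expected transition
Σ_a π(a|s) T[:, :, a] s.  Hard (argmax) rollouts are exposed for evaluation;
ties break toward the lowest action index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .dynamics import (
    ACTIVATION_DERIVS,
    ConditionLayout,
    get_activation,
)

__all__ = [
    "PolicyNet",
    "RecalibrationConfig",
    "RecalibrationReport",
    "CostModel",
    "rollout",
    "trajectory_mismatch",
    "condition_mismatch",
    "alignment_objective",
    "policy_action",
    "policy_logits",
    "policy_gradient_step",
    "kl_divergence",
    "total_objective",
    "recalibrate_window",
    "cumulative_alignment",
    "expected_step_cost",
    "window_loss",
    "window_loss_and_grad",
    "brute_force_window",
]


@dataclass(frozen=True)
class PolicyNet:
    """Two-layer perceptron from latent state (length d) to m action logits.

    Hidden nonlinearity is tanh; the action distribution is the softmax of
    the logits.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        for name in ("W1", "b1", "W2", "b2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.W1.shape[0] != self.b1.shape[0] or self.W2.shape[1] != self.W1.shape[0]:
            raise ValueError("inconsistent layer shapes")
        if self.W2.shape[0] != self.b2.shape[0]:
            raise ValueError("inconsistent output shapes")

    @property
    def d(self) -> int:
        return self.W1.shape[1]

    @property
    def m(self) -> int:
        return self.W2.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    @classmethod
    def init(cls, d: int, m: int, hidden_dim: int = 16, seed: int = 0,
             scale: float = 0.5) -> "PolicyNet":
        rng = np.random.default_rng(seed)
        return cls(
            W1=scale * rng.normal(size=(hidden_dim, d)) / np.sqrt(d),
            b1=np.zeros(hidden_dim),
            W2=scale * rng.normal(size=(m, hidden_dim)) / np.sqrt(hidden_dim),
            b2=np.zeros(m),
        )

    @classmethod
    def uniform_init(cls, d: int, m: int, hidden_dim: int = 16, seed: int = 0,
                     scale: float = 1.0) -> "PolicyNet":
        """Exactly uniform policy that is still trainable.

        Random first layer, zero output layer: logits are identically zero
        (so the action distribution is uniform at every state), while the
        hidden activations are nonzero, leaving a usable gradient path into
        the output weights.  An all-zero network would be a saddle where
        only the output bias can move.
        """
        rng = np.random.default_rng(seed)
        return cls(
            W1=scale * rng.normal(size=(hidden_dim, d)) / np.sqrt(d),
            b1=np.zeros(hidden_dim),
            W2=np.zeros((m, hidden_dim)),
            b2=np.zeros(m),
        )

    # -- flat parameter vector (for finite differences and generic steps) --

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def with_flat(self, flat: np.ndarray) -> "PolicyNet":
        h, d, m = self.hidden_dim, self.d, self.m
        i = 0
        W1 = flat[i : i + h * d].reshape(h, d); i += h * d
        b1 = flat[i : i + h]; i += h
        W2 = flat[i : i + m * h].reshape(m, h); i += m * h
        b2 = flat[i : i + m]
        return PolicyNet(W1, b1, W2, b2)


@dataclass(frozen=True)
class CostModel:
    """Continuous-state burden: quadratic deviation-from-healthy sᵀQs plus per-action cost."""

    state_cost: np.ndarray
    action_cost: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.state_cost, dtype=float)
        ac = np.asarray(self.action_cost, dtype=float)
        object.__setattr__(self, "state_cost", Q)
        object.__setattr__(self, "action_cost", ac)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("state_cost must be square")
        if np.max(np.abs(Q - Q.T)) > 1e-10:
            raise ValueError("state_cost must be symmetric")
        if np.linalg.eigvalsh(Q).min() < -1e-10:
            raise ValueError("state_cost must be positive semidefinite")
        if np.any(ac < 0):
            raise ValueError("action costs must be >= 0")

    @classmethod
    def zero(cls, d: int, m: int) -> "CostModel":
        return cls(np.zeros((d, d)), np.zeros(m))


@dataclass(frozen=True)
class RecalibrationConfig:
    """Planning-window settings: horizon H, cost tradeoff λ, KL coefficient β,
    learning rate η, per-condition weights, and iteration budget."""

    horizon: int = 3
    lam: float = 0.0
    beta: float = 0.0
    eta: float = 0.1
    weights: Optional[np.ndarray] = None  # per-condition; uniform when None
    iters: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.horizon < 1 or self.lam < 0 or self.beta < 0 or self.eta <= 0:
            raise ValueError("need horizon >= 1, lam >= 0, beta >= 0, eta > 0")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("condition weights must be >= 0")
            object.__setattr__(self, "weights", w)


@dataclass
class RecalibrationReport:
    delta_trace: np.ndarray
    objective_trace: np.ndarray
    kl_trace: np.ndarray
    final_policy: PolicyNet
    n_rejected: int = 0


# ------------------------------------------------------------ policy outputs


def policy_logits(s: np.ndarray, policy: PolicyNet) -> np.ndarray:
    return policy.W2 @ np.tanh(policy.W1 @ np.asarray(s, float) + policy.b1) + policy.b2


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def policy_action(s: np.ndarray, policy: PolicyNet) -> np.ndarray:
    """Categorical action distribution softmax(g_ω(s))."""
    logits = policy_logits(s, policy)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite policy logits")
    return _softmax(logits)


def kl_divergence(p_new: np.ndarray, p_old: np.ndarray) -> float:
    """KL(p_new ‖ p_old) with 0·ln 0 = 0; +inf when p_new has mass where p_old has none."""
    p = np.asarray(p_new, dtype=float)
    q = np.asarray(p_old, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    for v in (p, q):
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("inputs must be probability distributions")
    mask = p > 0
    if np.any(q[mask] <= 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


# ------------------------------------------------------------------ rollouts


def rollout(
    s_t: np.ndarray,
    policy: PolicyNet,
    T_p: np.ndarray,
    activation: str,
    H: int,
    mode: str = "argmax",
    seed: Optional[int] = None,
) -> np.ndarray:
    """Predicted latent path ŝ_t..ŝ_{t+H} under the policy (length H+1).

    ``argmax`` picks the modal action (ties → lowest index); ``sample``
    draws from the action distribution with the given seed; ``soft`` uses
    the policy-expected transition Σ_a π(a|s) T[:, :, a] s (the
    differentiable relaxation).
    """
    if H < 0:
        raise ValueError("horizon must be >= 0")
    sigma = get_activation(activation)
    rng = np.random.default_rng(seed) if mode == "sample" else None
    s = np.asarray(s_t, dtype=float)
    path = [s]
    for _ in range(H):
        pi = policy_action(s, policy)
        if mode == "argmax":
            s = sigma(T_p[:, :, int(np.argmax(pi))] @ s)
        elif mode == "sample":
            a = int(rng.choice(len(pi), p=pi))
            s = sigma(T_p[:, :, a] @ s)
        elif mode == "soft":
            s = sigma(np.einsum("a,ija,j->i", pi, T_p, s))
        else:
            raise ValueError(f"unknown rollout mode {mode!r}")
        path.append(s)
    return np.stack(path)


# ------------------------------------------------------- mismatch and costs


def trajectory_mismatch(pred: np.ndarray, inferred: np.ndarray) -> float:
    """Δ = Σ_τ ‖ŝ_τ − s_τ‖² between predicted and inferred latent paths."""
    pred = np.atleast_2d(np.asarray(pred, float))
    inferred = np.atleast_2d(np.asarray(inferred, float))
    if pred.shape != inferred.shape:
        raise ValueError(f"path shapes differ: {pred.shape} vs {inferred.shape}")
    return float(np.sum((pred - inferred) ** 2))


def condition_mismatch(
    pred: np.ndarray, inferred: np.ndarray, layout: ConditionLayout
) -> np.ndarray:
    """Per-condition mismatches Δ^(c); they sum to the total mismatch exactly."""
    pred = np.atleast_2d(np.asarray(pred, float))
    inferred = np.atleast_2d(np.asarray(inferred, float))
    if pred.shape != inferred.shape:
        raise ValueError(f"path shapes differ: {pred.shape} vs {inferred.shape}")
    if layout.d != pred.shape[1]:
        raise ValueError(f"layout covers {layout.d} dims, paths have {pred.shape[1]}")
    return np.array(
        [float(np.sum((pred[:, sl] - inferred[:, sl]) ** 2)) for sl in layout.slices()]
    )


def expected_step_cost(s: np.ndarray, action_dist: np.ndarray, cost: CostModel) -> float:
    """sᵀQs + Σ_a p(a)·action_cost[a]."""
    p = np.asarray(action_dist, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("action_dist must be a probability distribution")
    s = np.asarray(s, dtype=float)
    return float(s @ cost.state_cost @ s + p @ cost.action_cost)


def alignment_objective(
    deltas: Sequence[float],
    weights: Sequence[float],
    costs: Sequence[float],
    lam: float,
) -> float:
    """L = Σ_c w_c Δ^(c) + λ Σ_τ E[c(s_τ, a_τ)] — the minimized surrogate."""
    w = np.asarray(weights, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if len(w) != len(d):
        raise ValueError("one weight per condition mismatch required")
    if np.any(w < 0):
        raise ValueError("condition weights must be >= 0")
    return float(w @ d + lam * np.sum(np.asarray(costs, dtype=float)))


def cumulative_alignment(window_deltas: Sequence[float]) -> float:
    """Total alignment loss Σ_t Δ_t over all planning windows of a trajectory."""
    return float(np.sum(np.asarray(window_deltas, dtype=float)))


def total_objective(
    alignment: float,
    policy_new: PolicyNet,
    policy_old: PolicyNet,
    eval_states: np.ndarray,
    beta: float,
) -> float:
    """L_total = alignment + β · mean KL(π_new(s) ‖ π_old(s)) over eval states."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    states = np.atleast_2d(np.asarray(eval_states, float))
    kl = np.mean(
        [kl_divergence(policy_action(s, policy_new), policy_action(s, policy_old))
         for s in states]
    )
    return float(alignment + beta * kl)


# ----------------------------------------------------- window loss + gradient


def _coord_weights(layout: Optional[ConditionLayout], weights, d: int) -> np.ndarray:
    if layout is None:
        layout = ConditionLayout((d,))
    if weights is None:
        weights = np.ones(layout.C)
    w = np.asarray(weights, dtype=float)
    out = np.empty(d)
    for wc, sl in zip(w, layout.slices()):
        out[sl] = wc
    return out


def window_loss(
    policy: PolicyNet,
    s_t: np.ndarray,
    inferred: np.ndarray,
    T_p: np.ndarray,
    cost: CostModel,
    config: RecalibrationConfig,
    policy_old: Optional[PolicyNet] = None,
    layout: Optional[ConditionLayout] = None,
    activation: str = "tanh",
) -> float:
    """Scalar window objective under the soft rollout (reference for gradients)."""
    H = config.horizon
    pred = rollout(s_t, policy, T_p, activation, H, mode="soft")
    wvec = _coord_weights(layout, config.weights, pred.shape[1])
    loss = float(np.sum(wvec[None, :] * (pred - inferred) ** 2))
    for s in pred:
        loss += config.lam * expected_step_cost(s, policy_action(s, policy), cost)
    if config.beta > 0 and policy_old is not None:
        kl = np.mean(
            [kl_divergence(policy_action(s, policy), policy_action(s, policy_old))
             for s in inferred]
        )
        loss += config.beta * float(kl)
    return loss


def _mlp_forward(policy: PolicyNet, s: np.ndarray):
    z1 = policy.W1 @ s + policy.b1
    h = np.tanh(z1)
    logits = policy.W2 @ h + policy.b2
    pi = _softmax(logits)
    return z1, h, logits, pi


def _mlp_backward(policy: PolicyNet, s, h, dlogits, grads):
    """Accumulate parameter grads for a logits-adjoint at state s; return ds."""
    grads["W2"] += np.outer(dlogits, h)
    grads["b2"] += dlogits
    dh = policy.W2.T @ dlogits
    dz1 = dh * (1.0 - h**2)
    grads["W1"] += np.outer(dz1, s)
    grads["b1"] += dz1
    return policy.W1.T @ dz1


def window_loss_and_grad(
    policy: PolicyNet,
    s_t: np.ndarray,
    inferred: np.ndarray,
    T_p: np.ndarray,
    cost: CostModel,
    config: RecalibrationConfig,
    policy_old: Optional[PolicyNet] = None,
    layout: Optional[ConditionLayout] = None,
    activation: str = "tanh",
) -> tuple[float, np.ndarray]:
    """Window objective and its exact gradient in the flat parameter vector.

    Reverse-mode differentiation through the soft rollout: the chain runs
    through every policy evaluation along the predicted path, the expected
    transitions, the cost term, and the KL term at the (fixed) inferred
    states.  Agreement with central finite differences is part of the test
    contract.
    """
    H = config.horizon
    sigma = get_activation(activation)
    dsigma = ACTIVATION_DERIVS[activation]
    inferred = np.atleast_2d(np.asarray(inferred, float))
    if inferred.shape[0] != H + 1:
        raise ValueError(f"inferred path must have H+1 = {H + 1} states")
    d = policy.d
    wvec = _coord_weights(layout, config.weights, d)

    # ---- forward pass with caches
    s = np.asarray(s_t, dtype=float)
    states = [s]
    caches = []
    for _ in range(H):
        z1, h, logits, pi = _mlp_forward(policy, s)
        Ts = np.einsum("ija,j->ia", T_p, s)  # column a: T_a s
        u = Ts @ pi
        s_next = sigma(u)
        caches.append((s, z1, h, pi, Ts, u))
        states.append(s_next)
        s = s_next
    pred = np.stack(states)

    loss = float(np.sum(wvec[None, :] * (pred - inferred) ** 2))
    grads = {k: np.zeros_like(getattr(policy, k)) for k in ("W1", "b1", "W2", "b2")}

    # cost term: value, plus parameter grads from pi(s_tau) and state grads
    cost_state_adj = [np.zeros(d) for _ in range(H + 1)]
    if config.lam > 0:
        for tau, s_tau in enumerate(states):
            z1, h, logits, pi = _mlp_forward(policy, s_tau)
            loss += config.lam * float(s_tau @ cost.state_cost @ s_tau + pi @ cost.action_cost)
            dpi = config.lam * cost.action_cost
            dlogits = pi * (dpi - pi @ dpi)
            ds = _mlp_backward(policy, s_tau, h, dlogits, grads)
            cost_state_adj[tau] = config.lam * 2.0 * (cost.state_cost @ s_tau) + ds

    # KL trust region at the fixed inferred states
    if config.beta > 0 and policy_old is not None:
        n_eval = inferred.shape[0]
        for s_e in inferred:
            z1, h, logits, pi = _mlp_forward(policy, s_e)
            logp = logits - (logits.max() + np.log(np.sum(np.exp(logits - logits.max()))))
            lo = policy_logits(s_e, policy_old)
            logq = lo - (lo.max() + np.log(np.sum(np.exp(lo - lo.max()))))
            kl = float(pi @ (logp - logq))
            loss += config.beta * kl / n_eval
            dlogits = (config.beta / n_eval) * pi * ((logp - logq) - kl)
            _mlp_backward(policy, s_e, h, dlogits, grads)

    # ---- reverse pass through the rollout
    adj = 2.0 * wvec * (pred[H] - inferred[H]) + cost_state_adj[H]
    for tau in range(H - 1, -1, -1):
        s_tau, z1, h, pi, Ts, u = caches[tau]
        du = adj * dsigma(u)
        dpi = Ts.T @ du  # dL/dpi_a = du · (T_a s)
        dlogits = pi * (dpi - pi @ dpi)
        ds = _mlp_backward(policy, s_tau, h, dlogits, grads)
        M = np.einsum("ija,a->ij", T_p, pi)
        ds += M.T @ du
        adj = ds + 2.0 * wvec * (pred[tau] - inferred[tau]) + cost_state_adj[tau]

    flat_grad = np.concatenate(
        [grads["W1"].ravel(), grads["b1"], grads["W2"].ravel(), grads["b2"]]
    )
    return loss, flat_grad


def policy_gradient_step(
    policy: PolicyNet,
    loss_fn: Callable[[PolicyNet], float],
    eta: float,
    grad: Optional[np.ndarray] = None,
    fd_eps: float = 1e-6,
) -> PolicyNet:
    """One gradient-descent step ω ← ω − η ∇L(ω).

    When no analytic gradient is supplied the gradient is computed by
    central finite differences on the flat parameter vector — the slow but
    assumption-free route the analytic path is tested against.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if eta == 0:
        return policy
    if grad is None:
        flat = policy.flatten()
        grad = np.empty_like(flat)
        for i in range(len(flat)):
            up, dn = flat.copy(), flat.copy()
            up[i] += fd_eps
            dn[i] -= fd_eps
            grad[i] = (loss_fn(policy.with_flat(up)) - loss_fn(policy.with_flat(dn))) / (
                2 * fd_eps
            )
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite policy gradient")
    return policy.with_flat(policy.flatten() - eta * grad)


# ----------------------------------------------------------- recalibration


def recalibrate_window(
    s_t: np.ndarray,
    inferred: np.ndarray,
    policy: PolicyNet,
    T_p: np.ndarray,
    cost: CostModel,
    config: RecalibrationConfig,
    layout: Optional[ConditionLayout] = None,
    activation: str = "tanh",
    mode: str = "soft",
) -> RecalibrationReport:
    """Gradient recalibration of the policy over one planning window.

    Runs ``config.iters`` backtracking gradient steps on the soft-rollout
    objective (mismatch + λ·cost + β·KL against the window-start policy).
    ``delta_trace`` records the pure mismatch of the ``mode`` rollout at
    each iterate; ``kl_trace`` records the mean KL of the current policy
    against the window-start policy over the window's inferred states.
    Steps that cannot decrease the objective after exhausting backtracking
    are rejected (counted in ``n_rejected``), so the objective trace is
    non-increasing.
    """
    if mode not in ("soft", "hard"):
        raise ValueError(f"unknown mode {mode!r}")
    inferred = np.atleast_2d(np.asarray(inferred, float))
    if inferred.shape[0] != config.horizon + 1:
        raise ValueError(
            f"inferred path has {inferred.shape[0]} states, expected H+1 = {config.horizon + 1}"
        )
    policy_old = policy

    def delta_of(pol: PolicyNet) -> float:
        pred = rollout(s_t, pol, T_p, activation, config.horizon,
                       mode="argmax" if mode == "hard" else "soft")
        return trajectory_mismatch(pred, inferred)

    def kl_of(pol: PolicyNet) -> float:
        return float(np.mean(
            [kl_divergence(policy_action(s, pol), policy_action(s, policy_old))
             for s in inferred]
        ))

    loss, grad = window_loss_and_grad(
        policy, s_t, inferred, T_p, cost, config, policy_old, layout, activation
    )
    deltas, objs, kls = [delta_of(policy)], [loss], [kl_of(policy)]
    n_rejected = 0
    eta = config.eta
    for it in range(config.iters):
        if not np.isfinite(loss):
            raise FloatingPointError(f"recalibration diverged at iteration {it}")
        accepted = False
        trial = eta
        for _ in range(30):
            cand = policy.with_flat(policy.flatten() - trial * grad)
            cand_loss = window_loss(
                cand, s_t, inferred, T_p, cost, config, policy_old, layout, activation
            )
            if np.isfinite(cand_loss) and cand_loss < loss:
                accepted = True
                break
            trial *= 0.5
        if accepted:
            policy = cand
            loss, grad = window_loss_and_grad(
                policy, s_t, inferred, T_p, cost, config, policy_old, layout, activation
            )
            eta = min(trial * 2.0, config.eta * 100)
        else:
            n_rejected += 1
        deltas.append(delta_of(policy))
        objs.append(loss)
        kls.append(kl_of(policy))
    return RecalibrationReport(
        delta_trace=np.asarray(deltas),
        objective_trace=np.asarray(objs),
        kl_trace=np.asarray(kls),
        final_policy=policy,
        n_rejected=n_rejected,
    )


def brute_force_window(
    s_t: np.ndarray,
    inferred: np.ndarray,
    T_p: np.ndarray,
    activation: str,
    H: int,
    enumeration_cap: int = 100_000,
) -> tuple[tuple[int, ...], float]:
    """Exhaustive open-loop minimizer of the window mismatch (the planning oracle)."""
    sigma = get_activation(activation)
    m = T_p.shape[2]
    if m**H > enumeration_cap:
        raise ValueError(f"{m}^{H} sequences exceeds the cap {enumeration_cap}")
    inferred = np.atleast_2d(np.asarray(inferred, float))
    best_seq, best = None, np.inf
    seq = [0] * H
    for _ in range(m**H):
        s = np.asarray(s_t, float)
        delta = float(np.sum((s - inferred[0]) ** 2))
        for tau, a in enumerate(seq):
            s = sigma(T_p[:, :, a] @ s)
            delta += float(np.sum((s - inferred[tau + 1]) ** 2))
        if delta < best - 1e-15:
            best, best_seq = delta, tuple(seq)
        for i in range(H - 1, -1, -1):
            seq[i] += 1
            if seq[i] < m:
                break
            seq[i] = 0
    return best_seq, float(best)
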