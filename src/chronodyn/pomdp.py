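"""Exact finite-state partially observable Markov decision process.

Disease progression is modeled as a latent Markov chain over a small set of
discrete health states.  At each clinical visit an intervention (action) is
applied, the latent state moves according to an action-indexed transition
kernel, and a noisy discrete observation (a coded diagnostic finding) is
emitted.  The clinician never sees the state itself; the information state is
the *belief*, the posterior over latent states given the full history of
actions and observations, propagated by recursive Bayesian filtering.

This module is deliberately small and exact.  It serves two roles: a usable
model at desk scale, and the brute-force oracle against which the continuous
latent-dynamics machinery elsewhere in the package is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "DiscretePOMDP",
    "Belief",
    "History",
    "ImpossibleObservationError",
    "belief_update",
    "filter_history",
    "trajectory_cost",
    "expected_policy_cost",
    "brute_force_policy",
    "enumerate_path_posterior",
    "condition_on_observation",
]

_ATOL = 1e-12


class ImpossibleObservationError(ValueError):
    """Raised when an observation has zero probability under the predicted belief."""

    def __init__(self, action: int, obs: int, t: int | None = None):
        self.action = action
        self.obs = obs
        self.t = t
        where = f" at time index {t}" if t is not None else ""
        super().__init__(
            f"observation {obs} has zero probability after action {action}{where}; "
            "the model assigns no mass to any state that can emit it"
        )


@dataclass(frozen=True)
class DiscretePOMDP:
    """Finite POMDP: transition kernel, observation likelihood, cost table, discount.

    Parameters
    ----------
    trans : (n_states, n_actions, n_states) array
        ``trans[s, a, s']`` is P(s' | s, a); each ``[s, a, :]`` slice is a
        probability vector.
    obs_lik : (n_states, n_obs) array
        ``obs_lik[s, x]`` is P(x | s); rows are probability vectors.
    cost : (n_states, n_actions) array
        Nonnegative per-visit disease burden c(s, a).
    gamma : float
        Discount factor in [0, 1).
    """

    trans: np.ndarray
    obs_lik: np.ndarray
    cost: np.ndarray
    gamma: float

    def __post_init__(self):
        trans = np.asarray(self.trans, dtype=float)
        obs_lik = np.asarray(self.obs_lik, dtype=float)
        cost = np.asarray(self.cost, dtype=float)
        object.__setattr__(self, "trans", trans)
        object.__setattr__(self, "obs_lik", obs_lik)
        object.__setattr__(self, "cost", cost)
        if trans.ndim != 3 or trans.shape[0] != trans.shape[2]:
            raise ValueError(f"trans must be (n_states, n_actions, n_states), got {trans.shape}")
        n_states, n_actions, _ = trans.shape
        if obs_lik.ndim != 2 or obs_lik.shape[0] != n_states:
            raise ValueError(f"obs_lik must be (n_states, n_obs), got {obs_lik.shape}")
        if cost.shape != (n_states, n_actions):
            raise ValueError(f"cost must be (n_states, n_actions), got {cost.shape}")
        if np.any(trans < 0) or np.any(np.abs(trans.sum(axis=2) - 1.0) > _ATOL):
            raise ValueError("each trans[s, a, :] must be a probability vector")
        if np.any(obs_lik < 0) or np.any(np.abs(obs_lik.sum(axis=1) - 1.0) > _ATOL):
            raise ValueError("each obs_lik[s, :] must be a probability vector")
        if np.any(cost < 0):
            raise ValueError("cost must be nonnegative")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")

    @property
    def n_states(self) -> int:
        return self.trans.shape[0]

    @property
    def n_actions(self) -> int:
        return self.trans.shape[1]

    @property
    def n_obs(self) -> int:
        return self.obs_lik.shape[1]

    # -- JSON round trip (bit-stable for doubles: lists of Python floats) --

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "format_version": 1,
            "n_states": self.n_states,
            "n_obs": self.n_obs,
            "n_actions": self.n_actions,
            "gamma": self.gamma,
            "trans": self.trans.tolist(),
            "obs_lik": self.obs_lik.tolist(),
            "cost": self.cost.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "DiscretePOMDP":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            trans=np.array(payload["trans"], dtype=float),
            obs_lik=np.array(payload["obs_lik"], dtype=float),
            cost=np.array(payload["cost"], dtype=float),
            gamma=float(payload["gamma"]),
        )


@dataclass(frozen=True)
class Belief:
    """Posterior probability vector over latent states for one patient, one visit."""

    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1:
            raise ValueError("belief must be a vector")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > _ATOL:
            raise ValueError("belief entries must be >= 0 and sum to 1")

    @classmethod
    def uniform(cls, n_states: int) -> "Belief":
        return cls(np.full(n_states, 1.0 / n_states))


@dataclass(frozen=True)
class History:
    """Interleaved record of a patient's actions and observations.

    There is one more observation than actions: the record starts with the
    first observed finding, before any intervention is taken.
    """

    actions: tuple
    observations: tuple

    def __post_init__(self):
        object.__setattr__(self, "actions", tuple(int(a) for a in self.actions))
        object.__setattr__(self, "observations", tuple(int(x) for x in self.observations))
        if len(self.observations) != len(self.actions) + 1:
            raise ValueError(
                f"need len(observations) == len(actions) + 1, got "
                f"{len(self.observations)} observations / {len(self.actions)} actions"
            )


def belief_update(belief: Belief, action: int, obs: int, model: DiscretePOMDP) -> Belief:
    """One predict-then-correct Bayes step.

    Returns the normalized posterior b'(s') ∝ P(obs | s') Σ_s P(s' | s, action) b(s).
    Raises :class:`ImpossibleObservationError` when the observation has zero
    mass under the predicted belief (silent renormalization would hide model
    misspecification).
    """
    if not (0 <= action < model.n_actions):
        raise ValueError(f"action {action} out of range (m={model.n_actions})")
    if not (0 <= obs < model.n_obs):
        raise ValueError(f"observation {obs} out of range (|X|={model.n_obs})")
    predicted = belief.probs @ model.trans[:, action, :]
    unnorm = model.obs_lik[:, obs] * predicted
    mass = unnorm.sum()
    if mass <= 0.0:
        raise ImpossibleObservationError(action, obs)
    return Belief(unnorm / mass)


def condition_on_observation(prior: Belief, obs: int, model: DiscretePOMDP) -> Belief:
    """Bayes correction of a prior by a single observation (no transition)."""
    unnorm = prior.probs * model.obs_lik[:, obs]
    mass = unnorm.sum()
    if mass <= 0.0:
        raise ImpossibleObservationError(action=-1, obs=obs, t=0)
    return Belief(unnorm / mass)


def filter_history(
    history: History, model: DiscretePOMDP, prior: Belief | None = None
) -> list[Belief]:
    """Recursive Bayesian filtering over a full action/observation history.

    The belief at the first visit conditions the prior (uniform unless
    supplied) on the first observation; each later belief applies one
    :func:`belief_update` with the intervening action.  Returns one belief
    per observation.
    """
    if prior is None:
        prior = Belief.uniform(model.n_states)
    beliefs = [condition_on_observation(prior, history.observations[0], model)]
    for t, (a, x) in enumerate(zip(history.actions, history.observations[1:]), start=1):
        try:
            beliefs.append(belief_update(beliefs[-1], a, x, model))
        except ImpossibleObservationError as err:
            raise ImpossibleObservationError(a, x, t=t) from err
    return beliefs


def trajectory_cost(
    states: Sequence[int], actions: Sequence[int], model: DiscretePOMDP
) -> float:
    """Discounted disease burden Σ_t γ^{t-1} c(s_t, a_t) of a realized trajectory."""
    if len(states) != len(actions):
        raise ValueError(f"length mismatch: {len(states)} states vs {len(actions)} actions")
    if len(states) < 1:
        raise ValueError("need at least one (state, action) pair")
    s = np.asarray(states, dtype=int)
    a = np.asarray(actions, dtype=int)
    discounts = model.gamma ** np.arange(len(s))
    return float(np.sum(discounts * model.cost[s, a]))


PolicyLike = Union[Sequence[int], Callable[[Belief, int], int]]


def _open_loop_cost(actions: Sequence[int], model: DiscretePOMDP, p0: np.ndarray) -> float:
    """Exact expected discounted cost of a fixed action sequence.

    Observations do not influence an open-loop plan, so the expectation
    reduces to forward propagation of the state distribution.
    """
    p = p0.copy()
    total = 0.0
    disc = 1.0
    for a in actions:
        total += disc * float(p @ model.cost[:, a])
        p = p @ model.trans[:, a, :]
        disc *= model.gamma
    return total


def expected_policy_cost(
    policy: PolicyLike, model: DiscretePOMDP, horizon: int, initial: Belief
) -> float:
    """Exact expected discounted burden over ``horizon`` steps under a policy.

    ``policy`` is either a fixed action sequence (open loop) or a callable
    ``policy(belief, t) -> action`` (belief feedback).  Open-loop costs use
    forward propagation of the state distribution.  Belief policies are
    evaluated exactly by enumerating observation branches: each branch
    carries a conditional belief and its probability mass, so the result is
    the exact expectation, not a sample estimate.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not callable(policy):
        actions = list(policy)[:horizon]
        if len(actions) < horizon:
            raise ValueError("action sequence shorter than horizon")
        return _open_loop_cost(actions, model, initial.probs)

    total = 0.0
    # branches: (belief over states, unconditional probability of this branch)
    branches: list[tuple[np.ndarray, float]] = [(initial.probs.copy(), 1.0)]
    disc = 1.0
    for t in range(horizon):
        next_branches: list[tuple[np.ndarray, float]] = []
        for b, w in branches:
            a = int(policy(Belief(b), t))
            total += disc * w * float(b @ model.cost[:, a])
            if t == horizon - 1:
                continue
            predicted = b @ model.trans[:, a, :]
            for x in range(model.n_obs):
                unnorm = model.obs_lik[:, x] * predicted
                mass = unnorm.sum()
                if mass > 0.0:
                    next_branches.append((unnorm / mass, w * mass))
        branches = next_branches
        disc *= model.gamma
    return total


def brute_force_policy(
    model: DiscretePOMDP,
    horizon: int,
    initial: Belief,
    enumeration_cap: int = 100_000,
) -> tuple[tuple[int, ...], float]:
    """Exhaustive search over open-loop action sequences (the planning oracle).

    Returns the sequence minimizing exact expected discounted cost and that
    cost.  Ties break toward the lexicographically smallest sequence, which
    is the enumeration order of ``itertools.product``-style counting.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    n_seq = model.n_actions**horizon
    if n_seq > enumeration_cap:
        raise ValueError(
            f"{model.n_actions}^{horizon} = {n_seq} sequences exceeds the cap {enumeration_cap}"
        )
    best_seq: tuple[int, ...] | None = None
    best_cost = np.inf
    # lexicographic counting => first strict improvement wins ties
    seq = [0] * horizon
    for _ in range(n_seq):
        c = _open_loop_cost(seq, model, initial.probs)
        if c < best_cost - 1e-15:
            best_cost = c
            best_seq = tuple(seq)
        # increment like an odometer, most significant digit first
        for i in range(horizon - 1, -1, -1):
            seq[i] += 1
            if seq[i] < model.n_actions:
                break
            seq[i] = 0
    assert best_seq is not None
    return best_seq, float(best_cost)


def enumerate_path_posterior(history: History, model: DiscretePOMDP,
                             prior: Belief | None = None) -> np.ndarray:
    """Filtering posteriors by exhaustive summation over all latent paths.

    Independent oracle for :func:`filter_history`: enumerates every state
    sequence of length T, weights it by prior × transitions × emissions, and
    marginalizes.  Exponential in T; test scales only.  Returns an array of
    shape (T, n_states) where row t is P(s_t | history up to t).
    """
    if prior is None:
        prior = Belief.uniform(model.n_states)
    T = len(history.observations)
    n = model.n_states
    out = np.zeros((T, n))
    for t in range(T):
        # joint weight over paths (s_1..s_{t+1}) consistent with data up to t
        marg = np.zeros(n)
        for path in np.ndindex(*([n] * (t + 1))):
            w = prior.probs[path[0]] * model.obs_lik[path[0], history.observations[0]]
            for i in range(t):
                a = history.actions[i]
                w *= model.trans[path[i], a, path[i + 1]]
                w *= model.obs_lik[path[i + 1], history.observations[i + 1]]
            marg[path[t]] += w
        total = marg.sum()
        if total <= 0:
            raise ImpossibleObservationError(-1, history.observations[t], t=t)
        out[t] = marg / total
    return out
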