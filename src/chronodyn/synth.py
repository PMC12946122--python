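"""Synthetic longitudinal cohorts with known ground truth.

Every other module in the package is validated against data produced here:
a ground-truth prototype bank, per-patient simplex embeddings drawn from a
Dirichlet, deterministic latent paths under a behavior policy, and noisy
linear observations.  Nothing is downloaded; a cohort is a pure function of
its config (counter-based random streams keyed per patient, so adding
patients never perturbs existing ones).

The generator emulates encoder-output-like numeric observation vectors, not
raw clinical modalities: real EHR/imaging/sensor pipelines produce embedded
feature vectors, and those vectors are what the dynamics model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .dynamics import (
    ConditionLayout,
    EmissionModel,
    LatentDynamicsModel,
    PatientEmbedding,
    TensorBank,
    Trajectory,
    build_patient_tensor,
    emit,
    patient_emission_params,
    transition_step,
)
from .io import read_cohort, write_cohort  # re-exported: cohort I/O lives with the generator
from .pomdp import DiscretePOMDP

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_discrete_pomdp",
    "write_cohort",
    "read_cohort",
    "standard_benchmark_config",
]

# stream tags for the counter-based Philox keys
_TAG_MODEL = 0
_TAG_PATIENT = 1


def _stream(seed: int, tag: int, index: int = 0) -> np.random.Generator:
    """Independent Philox stream keyed by (seed, tag, index): order-independent."""
    return np.random.Generator(np.random.Philox(key=[seed & 0xFFFFFFFFFFFFFFFF,
                                                     (tag << 32) | index]))


@dataclass(frozen=True)
class CohortConfig:
    """Stated world for the synthetic cohort generator.

    Defaults give the standard desk-scale benchmark: 50 patients with 8-12
    visits, a 4-dimensional latent state mixing k=3 prototypes, 3
    interventions, 6 observed features, isotropic observation noise with
    standard deviation 0.1, and moderately mixed Dirichlet(1) embeddings.
    """

    n_patients: int = 50
    T_min: int = 8
    T_max: int = 12
    d: int = 4
    k: int = 3
    m: int = 3
    q: int = 6
    block_dims: Optional[tuple] = None  # defaults to a single block of size d
    noise_sd: float = 0.1
    full_cov: bool = False
    embedding_conc: float = 1.0
    behavior: str = "uniform"  # uniform | fixed-sequence | epsilon-greedy
    behavior_sequence: Optional[tuple] = None
    epsilon: float = 0.1
    activation: str = "tanh"
    spectral_bound: float = 0.95
    separation_floor: float = 0.3
    init_latent_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients, self.d, self.k, self.m, self.q, self.T_min) < 1:
            raise ValueError("all counts must be >= 1")
        if self.T_min > self.T_max:
            raise ValueError(f"T_min={self.T_min} > T_max={self.T_max}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.embedding_conc <= 0:
            raise ValueError("embedding_conc must be > 0")
        if self.behavior not in ("uniform", "fixed-sequence", "epsilon-greedy"):
            raise ValueError(f"unknown behavior policy {self.behavior!r}")
        if self.behavior == "fixed-sequence" and not self.behavior_sequence:
            raise ValueError("fixed-sequence behavior needs behavior_sequence")
        if self.block_dims is not None:
            object.__setattr__(self, "block_dims", tuple(int(x) for x in self.block_dims))
            if sum(self.block_dims) != self.d:
                raise ValueError(f"block_dims {self.block_dims} must sum to d={self.d}")

    @property
    def layout(self) -> ConditionLayout:
        return ConditionLayout(self.block_dims if self.block_dims else (self.d,))

    def to_dict(self) -> dict:
        out = asdict(self)
        if out["block_dims"] is not None:
            out["block_dims"] = list(out["block_dims"])
        if out["behavior_sequence"] is not None:
            out["behavior_sequence"] = list(out["behavior_sequence"])
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if d.get("block_dims") is not None:
            d["block_dims"] = tuple(d["block_dims"])
        if d.get("behavior_sequence") is not None:
            d["behavior_sequence"] = tuple(d["behavior_sequence"])
        return cls(**d)


@dataclass(frozen=True)
class Cohort:
    """Generated cohort: config echo, ground truth, and observed trajectories."""

    config: CohortConfig
    trajectories: list
    embeddings: list
    truth_model: Optional[LatentDynamicsModel]


def _draw_bank(cfg: CohortConfig, rng: np.random.Generator) -> TensorBank:
    """Prototype bank with spectral-norm-clipped slices and a Frobenius separation floor."""
    for _ in range(100):
        protos = rng.normal(0.0, 1.0 / np.sqrt(cfg.d), size=(cfg.k, cfg.d, cfg.d, cfg.m))
        for j in range(cfg.k):
            for a in range(cfg.m):
                norm = np.linalg.norm(protos[j, :, :, a], ord=2)
                if norm > cfg.spectral_bound:
                    protos[j, :, :, a] *= cfg.spectral_bound / norm
        ok = True
        for i in range(cfg.k):
            for j in range(i + 1, cfg.k):
                if np.linalg.norm(protos[i] - protos[j]) < cfg.separation_floor:
                    ok = False
        if ok:
            return TensorBank(protos, spectral_bound=cfg.spectral_bound)
    raise RuntimeError(
        f"could not draw {cfg.k} prototypes with pairwise Frobenius separation "
        f">= {cfg.separation_floor} in 100 attempts"
    )


def _draw_emission(cfg: CohortConfig, rng: np.random.Generator) -> EmissionModel:
    W = rng.normal(0.0, 1.0 / np.sqrt(cfg.d), size=(cfg.k, cfg.q, cfg.d))
    if cfg.full_cov:
        sigmas = np.empty((cfg.k, cfg.q, cfg.q))
        for j in range(cfg.k):
            A = rng.normal(size=(cfg.q, cfg.q)) / np.sqrt(cfg.q)
            S = A @ A.T
            # rescale so the mean marginal variance equals noise_sd^2
            S *= cfg.noise_sd**2 / max(np.trace(S) / cfg.q, 1e-300)
            sigmas[j] = S
    else:
        sigmas = np.broadcast_to(
            cfg.noise_sd**2 * np.eye(cfg.q), (cfg.k, cfg.q, cfg.q)
        ).copy()
    return EmissionModel(W, sigmas)


def _behavior_actions(
    cfg: CohortConfig,
    T: int,
    rng: np.random.Generator,
    policy: Optional[Callable[[np.ndarray], int]],
    latent_cb: Callable[[Sequence[int]], np.ndarray],
) -> np.ndarray:
    if cfg.behavior == "uniform":
        return rng.integers(0, cfg.m, size=T - 1)
    if cfg.behavior == "fixed-sequence":
        seq = np.asarray(cfg.behavior_sequence, dtype=int)
        return np.resize(seq, T - 1)
    # epsilon-greedy on a supplied latent-state policy
    if policy is None:
        raise ValueError("epsilon-greedy behavior needs a behavior_policy callable")
    actions: list[int] = []
    for t in range(T - 1):
        s = latent_cb(actions)
        if rng.random() < cfg.epsilon:
            actions.append(int(rng.integers(0, cfg.m)))
        else:
            actions.append(int(policy(s)))
    return np.asarray(actions, dtype=int)


def generate_cohort(
    config: CohortConfig,
    behavior_policy: Optional[Callable[[np.ndarray], int]] = None,
) -> Cohort:
    """Draw the ground-truth model and one trajectory per patient.

    All randomness derives from ``config.seed`` through per-patient Philox
    streams; the same config yields a bit-identical cohort.
    """
    cfg = config
    model_rng = _stream(cfg.seed, _TAG_MODEL)
    bank = _draw_bank(cfg, model_rng)
    emission = _draw_emission(cfg, model_rng)
    model = LatentDynamicsModel(
        bank=bank, emission=emission, layout=cfg.layout, activation=cfg.activation
    )

    trajectories, embeddings = [], []
    for p in range(cfg.n_patients):
        rng = _stream(cfg.seed, _TAG_PATIENT, p)
        z = PatientEmbedding(rng.dirichlet(np.full(cfg.k, cfg.embedding_conc)))
        T = int(rng.integers(cfg.T_min, cfg.T_max + 1))
        s1 = rng.normal(size=cfg.d) * cfg.init_latent_scale
        T_p = build_patient_tensor(z, bank)
        W_p, Sigma_p = patient_emission_params(z, emission)

        def roll(actions: Sequence[int]) -> np.ndarray:
            s = s1
            for a in actions:
                s = transition_step(s, a, T_p, cfg.activation)
            return s

        actions = _behavior_actions(cfg, T, rng, behavior_policy, roll)
        latents = [s1]
        for a in actions:
            latents.append(transition_step(latents[-1], a, T_p, cfg.activation))
        latents = np.stack(latents)
        noisy = cfg.noise_sd > 0
        obs = np.stack(
            [emit(s, W_p, Sigma_p, rng if noisy else None) for s in latents]
        )
        trajectories.append(
            Trajectory(actions=actions, observations=obs, latents=latents,
                       patient_id=f"p{p:04d}")
        )
        embeddings.append(z)
    return Cohort(config=cfg, trajectories=trajectories, embeddings=embeddings,
                  truth_model=model)


def standard_benchmark_config(n_patients: int, seed: int, T_min: int = 8,
                              T_max: int = 12) -> CohortConfig:
    """The standard parameter-recovery benchmark: k=3, d=4, q=6, noise_sd=0.1.

    Identity activation keeps the benchmark in the linear regime, where the
    alternating fit has closed-form blocks and identifiability (up to
    prototype permutation, given the emission bases) is well understood.
    """
    return CohortConfig(
        n_patients=n_patients, T_min=T_min, T_max=T_max,
        d=4, k=3, m=3, q=6, noise_sd=0.1, activation="identity", seed=seed,
    )


def generate_discrete_pomdp(
    n_states: int,
    n_obs: int,
    n_actions: int,
    gamma: float = 0.9,
    seed: int = 0,
    structure: str = "random",
) -> DiscretePOMDP:
    """Random or chain-structured finite POMDP fixture.

    ``random``: transition and observation rows drawn Dirichlet(1), costs
    uniform on [0, 1].  ``chain``: states are ordered disease-severity
    levels; action 0 lowers the level with probability 0.8 and action 1
    raises it with probability 0.8 (extra actions leave it unchanged), and
    cost increases with the level.
    """
    rng = _stream(seed, tag=7)
    if structure == "random":
        trans = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
        obs_lik = rng.dirichlet(np.ones(n_obs), size=n_states)
        cost = rng.uniform(0.0, 1.0, size=(n_states, n_actions))
    elif structure == "chain":
        trans = np.zeros((n_states, n_actions, n_states))
        for s in range(n_states):
            for a in range(n_actions):
                if a == 0:
                    target = max(s - 1, 0)
                elif a == 1 and n_actions > 1:
                    target = min(s + 1, n_states - 1)
                else:
                    target = s
                if target == s:
                    trans[s, a, s] = 1.0
                else:
                    trans[s, a, target] = 0.8
                    trans[s, a, s] = 0.2
        # observations: noisy reading of the severity level
        obs_lik = np.zeros((n_states, n_obs))
        for s in range(n_states):
            center = min(s, n_obs - 1)
            obs_lik[s, center] += 0.8
            obs_lik[s, (center + 1) % n_obs] += 0.1
            obs_lik[s, (center - 1) % n_obs] += 0.1
        # burden grows with severity; the lowering action carries a small cost
        sev = np.arange(n_states, dtype=float)
        cost = sev[:, None] + 0.1 * (np.arange(n_actions) == 0)[None, :]
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return DiscretePOMDP(trans=trans, obs_lik=obs_lik, cost=cost, gamma=gamma)
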