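"""Mixture-of-prototypes latent disease dynamics with shared-basis emission.

A cohort shares k *prototype* transition tensors (each d×d×m: latent-dim ×
latent-dim × interventions).  A patient is described by a simplex embedding
z ∈ Δ^{k-1}; their personal transition tensor is the convex combination
Σ_j z_j T_j, and likewise their emission matrix and observation-noise
covariance are convex combinations of k shared bases.  Latent states evolve
deterministically through an action-selected slice followed by a pointwise
nonlinearity; observations are a linear read-out plus Gaussian noise.

Multimorbidity is expressed as a block structure on the latent vector: each
chronic condition owns a sub-vector that evolves under its own tensor, and
the blocks are concatenated.

The prototype bank may optionally be stored in Tucker-factored form (see
:mod:`chronodyn.tucker`); dense and factored banks must induce identical
dynamics at full rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tucker import TuckerFactors, tucker_reconstruct

__all__ = [
    "TensorBank",
    "PatientEmbedding",
    "EmissionModel",
    "ConditionLayout",
    "LatentDynamicsModel",
    "Trajectory",
    "ACTIVATIONS",
    "build_patient_tensor",
    "transition_step",
    "blockwise_transition_step",
    "patient_emission_params",
    "emit",
    "simulate_trajectory",
    "smoothness_loss",
]

_SIMPLEX_ATOL = 1e-9

ACTIVATIONS = {
    "tanh": np.tanh,
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
}

ACTIVATION_DERIVS = {
    "tanh": lambda x: 1.0 - np.tanh(x) ** 2,
    "identity": lambda x: np.ones_like(x),
    "relu": lambda x: (x > 0).astype(float),
}


def get_activation(name: str):
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")


@dataclass(frozen=True)
class TensorBank:
    """k prototype transition tensors, each d×d×m, stacked as (k, d, d, m)."""

    prototypes: np.ndarray
    spectral_bound: Optional[float] = None

    def __post_init__(self):
        protos = np.asarray(self.prototypes, dtype=float)
        object.__setattr__(self, "prototypes", protos)
        if protos.ndim != 4 or protos.shape[1] != protos.shape[2]:
            raise ValueError(f"prototypes must be (k, d, d, m), got {protos.shape}")
        if self.spectral_bound is not None:
            for j in range(self.k):
                for a in range(self.m):
                    norm = np.linalg.norm(protos[j, :, :, a], ord=2)
                    if norm > self.spectral_bound + 1e-10:
                        raise ValueError(
                            f"prototype {j}, action {a}: spectral norm {norm:.6f} "
                            f"exceeds the configured bound {self.spectral_bound}"
                        )

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    @property
    def d(self) -> int:
        return self.prototypes.shape[1]

    @property
    def m(self) -> int:
        return self.prototypes.shape[3]

    def as_4way(self) -> np.ndarray:
        """The global tensor with modes (d, d, m, k)."""
        return np.moveaxis(self.prototypes, 0, -1)

    @classmethod
    def from_4way(cls, tensor: np.ndarray, spectral_bound: Optional[float] = None
                  ) -> "TensorBank":
        return cls(np.moveaxis(np.asarray(tensor, dtype=float), -1, 0), spectral_bound)


@dataclass(frozen=True)
class PatientEmbedding:
    """Simplex weights z placing one patient among the k prototypes."""

    z: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.ndim != 1:
            raise ValueError("embedding must be a vector")
        if np.any(z < -_SIMPLEX_ATOL) or abs(z.sum() - 1.0) > _SIMPLEX_ATOL:
            raise ValueError(
                f"embedding must lie on the probability simplex (sum={z.sum():.3g}, "
                f"min={z.min():.3g})"
            )

    @property
    def k(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class EmissionModel:
    """Shared emission bases: k read-out matrices (q×d) and k PSD noise covariances (q×q)."""

    bases_W: np.ndarray
    bases_Sigma: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.bases_W, dtype=float)
        S = np.asarray(self.bases_Sigma, dtype=float)
        object.__setattr__(self, "bases_W", W)
        object.__setattr__(self, "bases_Sigma", S)
        if W.ndim != 3:
            raise ValueError(f"bases_W must be (k, q, d), got {W.shape}")
        if S.shape != (W.shape[0], W.shape[1], W.shape[1]):
            raise ValueError(f"bases_Sigma must be (k, q, q), got {S.shape}")
        for j in range(S.shape[0]):
            if np.max(np.abs(S[j] - S[j].T)) > 1e-10:
                raise ValueError(f"Sigma basis {j} is not symmetric")
            if np.linalg.eigvalsh(S[j]).min() < -1e-10:
                raise ValueError(f"Sigma basis {j} is not positive semidefinite")

    @property
    def k(self) -> int:
        return self.bases_W.shape[0]

    @property
    def q(self) -> int:
        return self.bases_W.shape[1]

    @property
    def d(self) -> int:
        return self.bases_W.shape[2]


@dataclass(frozen=True)
class ConditionLayout:
    """Partition of the latent vector into per-condition blocks of sizes d_1..d_C."""

    block_dims: tuple

    def __post_init__(self):
        dims = tuple(int(x) for x in self.block_dims)
        object.__setattr__(self, "block_dims", dims)
        if len(dims) < 1 or any(x < 1 for x in dims):
            raise ValueError("block_dims must be >= 1 positive integers")

    @property
    def C(self) -> int:
        return len(self.block_dims)

    @property
    def d(self) -> int:
        return sum(self.block_dims)

    def slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.block_dims)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class LatentDynamicsModel:
    """Full population model: prototype bank, emission bases, condition layout, nonlinearity.

    ``bank`` may be a dense :class:`TensorBank` or :class:`TuckerFactors`
    over the 4-way (d, d, m, k) global tensor; both must induce the same
    dynamics (exactly, at full rank).
    """

    bank: object  # TensorBank | TuckerFactors
    emission: EmissionModel
    layout: ConditionLayout
    activation: str = "tanh"

    def __post_init__(self):
        get_activation(self.activation)
        b = self.dense_bank()
        if b.d != self.emission.d or b.k != self.emission.k:
            raise ValueError(
                f"bank (d={b.d}, k={b.k}) and emission (d={self.emission.d}, "
                f"k={self.emission.k}) disagree"
            )
        if self.layout.d != b.d:
            raise ValueError(f"layout sums to {self.layout.d}, latent dim is {b.d}")

    def dense_bank(self) -> TensorBank:
        if isinstance(self.bank, TensorBank):
            return self.bank
        if isinstance(self.bank, TuckerFactors):
            return TensorBank.from_4way(tucker_reconstruct(self.bank))
        raise TypeError(f"bank must be TensorBank or TuckerFactors, got {type(self.bank)}")

    @property
    def d(self) -> int:
        return self.emission.d

    @property
    def q(self) -> int:
        return self.emission.q

    @property
    def k(self) -> int:
        return self.emission.k

    @property
    def m(self) -> int:
        return self.dense_bank().m


@dataclass(frozen=True)
class Trajectory:
    """One patient's visit-indexed actions, observations, and optional true latents.

    ``observations`` has shape (T, q); ``actions`` has length T-1 (the action
    taken between consecutive visits); ``latents``, when present, has shape
    (T, d).
    """

    actions: np.ndarray
    observations: np.ndarray
    latents: Optional[np.ndarray] = None
    patient_id: Optional[str] = None

    def __post_init__(self):
        a = np.asarray(self.actions, dtype=int)
        x = np.atleast_2d(np.asarray(self.observations, dtype=float))
        object.__setattr__(self, "actions", a)
        object.__setattr__(self, "observations", x)
        if self.latents is not None:
            s = np.atleast_2d(np.asarray(self.latents, dtype=float))
            object.__setattr__(self, "latents", s)
            if s.shape[0] != x.shape[0]:
                raise ValueError("latents and observations must cover the same visits")
        if len(a) != x.shape[0] - 1:
            raise ValueError(
                f"need len(actions) == T-1, got {len(a)} actions for {x.shape[0]} visits"
            )

    @property
    def T(self) -> int:
        return self.observations.shape[0]


def build_patient_tensor(z: PatientEmbedding, bank: TensorBank) -> np.ndarray:
    """Patient-specific d×d×m tensor as the convex combination Σ_j z_j T_j."""
    if z.k != bank.k:
        raise ValueError(f"embedding length {z.k} != prototype count {bank.k}")
    return np.tensordot(z.z, bank.prototypes, axes=(0, 0))


def transition_step(
    s: np.ndarray, action: int, T_p: np.ndarray, activation: str = "tanh"
) -> np.ndarray:
    """One latent step s' = σ(T_p[:, :, action] · s)."""
    sigma = get_activation(activation)
    s = np.asarray(s, dtype=float)
    if T_p.shape[0] != T_p.shape[1] or T_p.shape[0] != s.shape[0]:
        raise ValueError(f"tensor {T_p.shape} incompatible with state of length {s.shape[0]}")
    if not (0 <= action < T_p.shape[2]):
        raise ValueError(f"action {action} out of range for m={T_p.shape[2]}")
    return sigma(T_p[:, :, action] @ s)


def blockwise_transition_step(
    s: np.ndarray,
    action: int,
    block_tensors: Sequence[np.ndarray],
    layout: ConditionLayout,
    activation: str = "tanh",
) -> np.ndarray:
    """Per-condition latent step: each block evolves under its own tensor."""
    s = np.asarray(s, dtype=float)
    if len(block_tensors) != layout.C:
        raise ValueError(f"{len(block_tensors)} tensors for {layout.C} blocks")
    if layout.d != s.shape[0]:
        raise ValueError(f"layout covers {layout.d} dims, state has {s.shape[0]}")
    out = np.empty_like(s)
    for sl, dim, Tc in zip(layout.slices(), layout.block_dims, block_tensors):
        if Tc.shape[0] != dim or Tc.shape[1] != dim:
            raise ValueError(f"block tensor {Tc.shape} does not match block size {dim}")
        out[sl] = transition_step(s[sl], action, Tc, activation)
    return out


def patient_emission_params(
    z: PatientEmbedding, emission: EmissionModel
) -> tuple[np.ndarray, np.ndarray]:
    """Patient read-out matrix W_p = Σ_j z_j W_j and noise covariance Σ_p = Σ_j z_j Σ_j.

    Σ_p is PSD automatically: a convex combination of PSD matrices.
    """
    if z.k != emission.k:
        raise ValueError(f"embedding length {z.k} != basis count {emission.k}")
    W_p = np.tensordot(z.z, emission.bases_W, axes=(0, 0))
    Sigma_p = np.tensordot(z.z, emission.bases_Sigma, axes=(0, 0))
    return W_p, Sigma_p


def emit(
    s: np.ndarray,
    W_p: np.ndarray,
    Sigma_p: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Observation x = W_p s + ε, ε ~ N(0, Σ_p).  ``rng=None`` disables noise."""
    s = np.asarray(s, dtype=float)
    mean = W_p @ s
    if rng is None or not np.any(Sigma_p):
        return mean
    eigvals = np.linalg.eigvalsh(Sigma_p)
    if eigvals.min() < -1e-10:
        raise ValueError("Sigma_p is not positive semidefinite")
    return rng.multivariate_normal(mean, Sigma_p, method="cholesky" if eigvals.min() > 1e-12
                                   else "eigh")


def simulate_trajectory(
    model: LatentDynamicsModel,
    z: PatientEmbedding,
    s1: np.ndarray,
    actions: Sequence[int],
    noise: bool = True,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Roll the generative model forward from s1 under a fixed action sequence.

    The latent path is deterministic; only the emission adds noise.  The same
    seed yields bit-identical output.
    """
    actions = list(actions)
    if len(actions) < 1:
        raise ValueError("need at least one action")
    if noise and rng is None:
        rng = np.random.default_rng(seed)
    T_p = build_patient_tensor(z, model.dense_bank())
    W_p, Sigma_p = patient_emission_params(z, model.emission)
    s = np.asarray(s1, dtype=float)
    latents = [s]
    for a in actions:
        s = transition_step(s, a, T_p, model.activation)
        latents.append(s)
    latents = np.stack(latents)
    obs = np.stack([emit(st, W_p, Sigma_p, rng if noise else None) for st in latents])
    return Trajectory(actions=np.asarray(actions), observations=obs, latents=latents)


def smoothness_loss(latents: Sequence[np.ndarray]) -> float:
    """Temporal-coherence penalty Σ_t ‖s_{t+1} − s_t‖²; zero iff the path is constant."""
    arr = np.atleast_2d(np.asarray(latents, dtype=float))
    if arr.shape[0] < 2:
        return 0.0
    return float(np.sum(np.diff(arr, axis=0) ** 2))
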