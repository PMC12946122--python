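"""Fitting the latent dynamics model and inferring per-patient quantities.

The generative model (``chronodyn.dynamics``) gives structure but no full
likelihood, so fitting uses penalized least squares: a Gaussian
observation-error term, a model-consistency penalty on deviations of the
latent path from the deterministic dynamics, and an optional raw
step-difference smoothness penalty.  Training is alternating minimization
over (prototype bank, emission bases), per-patient simplex embeddings, and
per-patient latent paths; every accepted block update decreases the global
objective, so the objective trace is monotone by construction.

In the identity-activation (linear) regime every block has a closed form:
latent paths solve a quadratic program, and bank/emission solve ordinary
least squares on Kronecker features — which is exactly the regime where the
closed-form oracle tests live.  Nonlinear activations fall back to
backtracking gradient steps for the non-quadratic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .dynamics import (
    ACTIVATION_DERIVS,
    ACTIVATIONS,
    ConditionLayout,
    EmissionModel,
    LatentDynamicsModel,
    PatientEmbedding,
    TensorBank,
    Trajectory,
    build_patient_tensor,
    get_activation,
    patient_emission_params,
    transition_step,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "infer_latents",
    "estimate_embedding",
    "fit_dynamics",
    "predictive_mse",
]


@dataclass(frozen=True)
class FitConfig:
    """Knobs for the alternating fit.

    ``smooth_weight`` multiplies the literal step-difference penalty
    Σ‖s_{t+1}−s_t‖²; ``consistency_weight`` multiplies the model-consistency
    penalty Σ‖s_{t+1}−σ(T_p s_t)‖².  Both are kept as separate weights.
    """

    smooth_weight: float = 0.0
    consistency_weight: float = 1.0
    max_iters: int = 30
    step_size: float = 0.1
    tol: float = 1e-8
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self):
        if self.smooth_weight < 0 or self.consistency_weight < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.max_iters < 1 or self.step_size <= 0 or self.tol <= 0:
            raise ValueError("need max_iters >= 1, step_size > 0, tol > 0")


@dataclass
class FitResult:
    model: LatentDynamicsModel
    embeddings: list
    latents: list
    objective_trace: np.ndarray
    converged: bool


# ------------------------------------------------------------- latent paths


def _path_objective(
    S: np.ndarray,
    traj: Trajectory,
    W: np.ndarray,
    P: np.ndarray,
    T_p: np.ndarray,
    activation: str,
    w_dyn: float,
    w_step: float,
) -> float:
    sigma = get_activation(activation)
    resid = traj.observations - S @ W.T
    obj = float(np.einsum("ti,ij,tj->", resid, P, resid))
    if len(traj.actions) > 0:
        A = T_p[:, :, traj.actions]  # (d, d, T-1)
        U = np.einsum("ijt,tj->ti", A, S[:-1])
        obj += w_dyn * float(np.sum((S[1:] - sigma(U)) ** 2))
        obj += w_step * float(np.sum((S[1:] - S[:-1]) ** 2))
    return obj


def _path_gradient(S, traj, W, P, T_p, activation, w_dyn, w_step):
    sigma = get_activation(activation)
    dsigma = ACTIVATION_DERIVS[activation]
    grad = -2.0 * (traj.observations - S @ W.T) @ P @ W
    if len(traj.actions) > 0:
        A = T_p[:, :, traj.actions]
        U = np.einsum("ijt,tj->ti", A, S[:-1])
        R = S[1:] - sigma(U)
        grad[1:] += 2.0 * w_dyn * R
        grad[:-1] -= 2.0 * w_dyn * np.einsum("ijt,ti->tj", A, dsigma(U) * R)
        D = S[1:] - S[:-1]
        grad[1:] += 2.0 * w_step * D
        grad[:-1] -= 2.0 * w_step * D
    return grad


def _solve_quadratic_path(traj, W, P, T_p, w_dyn, w_step) -> np.ndarray:
    """Exact minimizer of the path objective when the activation is the identity.

    The objective is a positive semidefinite quadratic in the stacked path;
    solved as one dense least-squares-style linear system (T·d unknowns,
    desk scale).
    """
    T, d = traj.T, W.shape[1]
    n = T * d
    H = np.zeros((n, n))
    g = np.zeros(n)
    WtPW = W.T @ P @ W
    WtP = W.T @ P
    for t in range(T):
        sl = slice(t * d, (t + 1) * d)
        H[sl, sl] += WtPW
        g[sl] += WtP @ traj.observations[t]
    I = np.eye(d)
    for t in range(T - 1):
        a = int(traj.actions[t])
        A = T_p[:, :, a]
        s0 = slice(t * d, (t + 1) * d)
        s1 = slice((t + 1) * d, (t + 2) * d)
        for wgt, B in ((w_dyn, A), (w_step, I)):
            if wgt == 0:
                continue
            H[s1, s1] += wgt * I
            H[s0, s0] += wgt * B.T @ B
            H[s1, s0] -= wgt * B
            H[s0, s1] -= wgt * B.T
    sol = np.linalg.lstsq(H, g, rcond=None)[0]
    return sol.reshape(T, d)


def _forward_simulated_init(traj, W, P, T_p, activation) -> np.ndarray:
    """Initial path: least-squares s1 from x1, then forward-simulate the dynamics."""
    s = np.linalg.lstsq(W, traj.observations[0], rcond=None)[0]
    path = [s]
    for a in traj.actions:
        s = transition_step(s, int(a), T_p, activation)
        path.append(s)
    return np.stack(path)


def infer_latents(
    traj: Trajectory,
    z: PatientEmbedding,
    model: LatentDynamicsModel,
    smooth_weight: float = 1.0,
    step_weight: float = 0.0,
    max_iters: int = 500,
    step_size: float = 0.05,
    tol: float = 1e-10,
    init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Smoothed latent path for one patient under a fixed model and embedding.

    Minimizes Σ_t ‖x_t − W_p s_t‖²_{Σ_p⁻¹} + ``smooth_weight``·Σ_t
    ‖s_{t+1} − σ(T_p s_t)‖² (+ ``step_weight`` times the raw step penalty),
    starting from the forward-simulated path.  Identity activation is solved
    exactly; otherwise backtracking gradient descent, so the returned
    objective never exceeds the initialization's.
    """
    T_p = build_patient_tensor(z, model.dense_bank())
    W, Sigma = patient_emission_params(z, model.emission)
    if np.any(Sigma):
        P = np.linalg.pinv(Sigma)
    else:
        P = np.eye(W.shape[0])
    args = (traj, W, P, T_p, model.activation, smooth_weight, step_weight)

    S = _forward_simulated_init(traj, W, P, T_p, model.activation) if init is None else init.copy()
    f0 = _path_objective(S, *args)
    if model.activation == "identity":
        S_exact = _solve_quadratic_path(traj, W, P, T_p, smooth_weight, step_weight)
        return S_exact if _path_objective(S_exact, *args) <= f0 else S

    f = f0
    step = step_size
    for _ in range(max_iters):
        grad = _path_gradient(S, *args)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient in latent-path smoothing")
        gnorm2 = float(np.sum(grad**2))
        if gnorm2 < tol:
            break
        accepted = False
        trial_step = step
        for _ in range(40):
            S_new = S - trial_step * grad
            f_new = _path_objective(S_new, *args)
            if np.isfinite(f_new) and f_new < f:
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            break
        if f - f_new < tol * max(1.0, abs(f)):
            S, f = S_new, f_new
            break
        S, f, step = S_new, f_new, min(trial_step * 2.0, 1.0)
    if not np.isfinite(f):
        raise FloatingPointError("latent-path smoothing diverged")
    return S


# ---------------------------------------------------------------- embeddings


def _one_step_pred_error(z_vec: np.ndarray, traj: Trajectory,
                         model: LatentDynamicsModel) -> float:
    """One-step-ahead observation prediction error under embedding z.

    Latents are read off per visit by least squares against W(z); the next
    observation is predicted through the z-mixed dynamics and read-out.
    """
    z = PatientEmbedding(np.clip(z_vec, 0.0, None) / max(np.sum(np.clip(z_vec, 0.0, None)), 1e-300))
    T_p = build_patient_tensor(z, model.dense_bank())
    W, _ = patient_emission_params(z, model.emission)
    sigma = get_activation(model.activation)
    S_hat = np.linalg.lstsq(W, traj.observations.T, rcond=None)[0].T
    err = 0.0
    for t in range(traj.T - 1):
        pred = W @ sigma(T_p[:, :, int(traj.actions[t])] @ S_hat[t])
        err += float(np.sum((traj.observations[t + 1] - pred) ** 2))
    return err


def _simplex_grid(k: int, resolution: float) -> np.ndarray:
    n = max(int(round(1.0 / resolution)), 1)

    def comps(total, parts):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for tail in comps(total - head, parts - 1):
                yield (head, *tail)

    return np.array([np.array(c, dtype=float) / n for c in comps(n, k)])


def estimate_embedding(
    traj: Trajectory,
    model: LatentDynamicsModel,
    method: str = "gradient",
    grid_resolution: float = 0.05,
    max_iters: int = 200,
    full_output: bool = False,
):
    """Simplex embedding minimizing one-step-ahead observation prediction error.

    ``method="grid"`` scans a simplex lattice (the test oracle);
    ``method="gradient"`` optimizes a softmax reparameterization z =
    softmax(v) with backtracking gradient descent (finite-difference
    gradients in v; k is small).  When the objective is flat across the
    prototype vertices the estimate is flagged non-identifiable.
    """
    if traj.T < 2:
        raise ValueError("need a trajectory of length >= 2 to estimate an embedding")
    k = model.k
    if k == 1:
        z = PatientEmbedding(np.array([1.0]))
        return (z, {"objective": _one_step_pred_error(z.z, traj, model),
                    "non_identifiable": False}) if full_output else z

    vertex_objs = [
        _one_step_pred_error(np.eye(k)[j], traj, model) for j in range(k)
    ]
    spread = max(vertex_objs) - min(vertex_objs)
    non_ident = spread <= 1e-12 * (1.0 + abs(max(vertex_objs)))

    if method == "grid":
        grid = _simplex_grid(k, grid_resolution)
        objs = np.array([_one_step_pred_error(zv, traj, model) for zv in grid])
        best = int(np.argmin(objs))
        z = PatientEmbedding(grid[best])
        info = {"objective": float(objs[best]), "non_identifiable": bool(non_ident)}
        return (z, info) if full_output else z
    if method != "gradient":
        raise ValueError(f"unknown method {method!r}")

    def obj_v(v):
        e = np.exp(v - v.max())
        return _one_step_pred_error(e / e.sum(), traj, model)

    v = np.zeros(k)
    f = obj_v(v)
    step = 0.5
    h = 1e-6
    for _ in range(max_iters):
        grad = np.empty(k)
        for j in range(k):
            ev = np.zeros(k)
            ev[j] = h
            grad[j] = (obj_v(v + ev) - obj_v(v - ev)) / (2 * h)
        if np.linalg.norm(grad) < 1e-12:
            break
        accepted = False
        trial = step
        for _ in range(30):
            v_new = v - trial * grad
            f_new = obj_v(v_new)
            if f_new < f:
                accepted = True
                break
            trial *= 0.5
        if not accepted or f - f_new < 1e-14 * max(1.0, abs(f)):
            if accepted:
                v, f = v_new, f_new
            break
        v, f, step = v_new, f_new, min(trial * 2.0, 10.0)
    e = np.exp(v - v.max())
    z = PatientEmbedding(e / e.sum())
    info = {"objective": float(f), "non_identifiable": bool(non_ident)}
    return (z, info) if full_output else z


# ------------------------------------------------------------- the joint fit


def _global_objective(trajs, S_list, z_list, bank, W_bases, cfg, activation):
    total = 0.0
    for traj, S, z in zip(trajs, S_list, z_list):
        W = np.tensordot(z.z, W_bases, axes=(0, 0))
        T_p = build_patient_tensor(z, bank)
        total += _path_objective(
            S, traj, W, np.eye(W.shape[0]), T_p, activation,
            cfg.consistency_weight, cfg.smooth_weight,
        )
    return total


def _ls_update_params(trajs, S_list, z_list, k, d, m, q, w_dyn, fit_emission,
                      W_bases_old):
    """Closed-form bank/emission update in the identity-activation regime.

    Both the transition and emission mixtures are linear in the parameters
    with features kron(z, s_t), so each reduces to ordinary least squares
    (per action for the bank, pooled for the emission).
    """
    protos = np.zeros((k, d, d, m))
    for a in range(m):
        feats, targets = [], []
        for traj, S, z in zip(trajs, S_list, z_list):
            idx = np.where(traj.actions == a)[0]
            if len(idx) == 0:
                continue
            feats.append(np.einsum("j,ti->tji", z.z, S[idx]).reshape(len(idx), k * d))
            targets.append(S[idx + 1])
        if not feats:
            continue
        F = np.concatenate(feats)
        Y = np.concatenate(targets)
        coef = np.linalg.lstsq(F, Y, rcond=None)[0]  # (k*d, d)
        protos[:, :, :, a] = coef.reshape(k, d, d).transpose(0, 2, 1)
    if fit_emission:
        feats, targets = [], []
        for traj, S, z in zip(trajs, S_list, z_list):
            feats.append(np.einsum("j,ti->tji", z.z, S).reshape(traj.T, k * d))
            targets.append(traj.observations)
        F = np.concatenate(feats)
        Y = np.concatenate(targets)
        coef = np.linalg.lstsq(F, Y, rcond=None)[0]
        W_bases = coef.reshape(k, d, q).transpose(0, 2, 1)
    else:
        W_bases = W_bases_old
    return protos, W_bases


def _grad_update_bank(trajs, S_list, z_list, bank_protos, activation, w_dyn,
                      n_steps=5, step0=0.05):
    """Backtracking gradient steps on the prototype bank (nonlinear activations)."""
    sigma = ACTIVATIONS[activation]
    dsigma = ACTIVATION_DERIVS[activation]
    k, d, _, m = bank_protos.shape

    def obj(P):
        total = 0.0
        for traj, S, z in zip(trajs, S_list, z_list):
            T_p = np.tensordot(z.z, P, axes=(0, 0))
            A = T_p[:, :, traj.actions]
            U = np.einsum("ijt,tj->ti", A, S[:-1])
            total += float(np.sum((S[1:] - sigma(U)) ** 2))
        return w_dyn * total

    P = bank_protos.copy()
    f = obj(P)
    step = step0
    for _ in range(n_steps):
        G = np.zeros_like(P)
        for traj, S, z in zip(trajs, S_list, z_list):
            T_p = np.tensordot(z.z, P, axes=(0, 0))
            A = T_p[:, :, traj.actions]
            U = np.einsum("ijt,tj->ti", A, S[:-1])
            R = (S[1:] - sigma(U)) * dsigma(U)  # (T-1, d)
            for t, a in enumerate(traj.actions):
                outer = np.outer(R[t], S[t])  # dJ/dT_p slice, sans -2 w
                G[:, :, :, int(a)] -= 2.0 * w_dyn * z.z[:, None, None] * outer
        accepted = False
        trial = step
        for _ in range(30):
            P_new = P - trial * G
            f_new = obj(P_new)
            if f_new < f:
                accepted = True
                break
            trial *= 0.5
        if not accepted:
            break
        P, f, step = P_new, f_new, min(trial * 2.0, 1.0)
    return P


def _update_embedding(traj, S, z0, bank, W_bases, cfg, activation):
    k = len(z0.z)
    if k == 1:
        return z0

    def obj(zv):
        z = PatientEmbedding(np.clip(zv, 0, None) / max(np.clip(zv, 0, None).sum(), 1e-300))
        W = np.tensordot(z.z, W_bases, axes=(0, 0))
        T_p = build_patient_tensor(z, bank)
        return _path_objective(S, traj, W, np.eye(W.shape[0]), T_p, activation,
                               cfg.consistency_weight, cfg.smooth_weight)

    res = minimize(
        obj, z0.z, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda zv: zv.sum() - 1.0}],
        options={"maxiter": 50, "ftol": 1e-12},
    )
    if res.success and obj(res.x) < obj(z0.z):
        zv = np.clip(res.x, 0.0, None)
        return PatientEmbedding(zv / zv.sum())
    return z0


def fit_dynamics(
    trajectories: Sequence[Trajectory],
    k: int,
    d: int,
    config: FitConfig,
    m: Optional[int] = None,
    activation: str = "identity",
    layout: Optional[ConditionLayout] = None,
    emission_init: Optional[EmissionModel] = None,
    fix_emission: bool = False,
    use_given_latents: bool = True,
) -> FitResult:
    """Alternating-minimization fit of the mixture-of-prototypes model.

    Blocks: (prototype bank, emission bases) given latents and embeddings —
    closed-form least squares under the identity activation, backtracking
    gradient steps otherwise; per-patient simplex embeddings by constrained
    optimization; per-patient latent paths by the quadratic/gradient
    smoother.  A block update is kept only if the global objective does not
    increase, so ``objective_trace`` is non-increasing.  Fully deterministic
    given ``config.seed``.

    When trajectories carry ground-truth latents and ``use_given_latents``
    is set, they serve as the latent initialization; ``fix_emission`` pins
    the emission bases at ``emission_init`` (the known-emission recovery
    regime).
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("cohort is empty")
    q = trajs[0].observations.shape[1]
    if any(tr.observations.shape[1] != q for tr in trajs):
        raise ValueError("all trajectories must share the observation dimension q")
    if m is None:
        m = int(max((tr.actions.max(initial=0) for tr in trajs))) + 1
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = layout or ConditionLayout((d,))

    # --- initialization -----------------------------------------------------
    if emission_init is not None:
        W_bases = emission_init.bases_W.copy()
    else:
        # PCA-style: scores of the pooled observations span the latent space
        X = np.concatenate([tr.observations for tr in trajs])
        _, sv, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        W0 = Vt[:d].T if Vt.shape[0] >= d else np.pad(Vt.T, ((0, 0), (0, d - Vt.shape[0])))
        W_bases = np.stack([W0 + cfg.init_scale * rng.normal(size=(q, d)) / np.sqrt(d)
                            for _ in range(k)])
    protos = cfg.init_scale * rng.normal(size=(k, d, d, m)) / np.sqrt(d)
    z_list = [PatientEmbedding(np.full(k, 1.0 / k)) for _ in trajs]

    S_list = []
    for tr, z in zip(trajs, z_list):
        if use_given_latents and tr.latents is not None:
            S_list.append(tr.latents.astype(float).copy())
        else:
            W = np.tensordot(z.z, W_bases, axes=(0, 0))
            S_list.append(np.linalg.lstsq(W, tr.observations.T, rcond=None)[0].T)

    def objective(P, Wb, zs, Ss):
        return _global_objective(trajs, Ss, zs, TensorBank(P), Wb, cfg, activation)

    f = objective(protos, W_bases, z_list, S_list)
    trace = [f]
    converged = False
    fit_emission = not fix_emission

    for it in range(cfg.max_iters):
        # block 1: bank + emission
        if activation == "identity":
            protos_new, W_new = _ls_update_params(
                trajs, S_list, z_list, k, d, m, q, cfg.consistency_weight,
                fit_emission, W_bases,
            )
        else:
            protos_new = _grad_update_bank(
                trajs, S_list, z_list, protos, activation, cfg.consistency_weight,
            )
            if fit_emission:
                _, W_new = _ls_update_params(
                    trajs, S_list, z_list, k, d, m, q, cfg.consistency_weight,
                    True, W_bases,
                )
            else:
                W_new = W_bases
        f_new = objective(protos_new, W_new, z_list, S_list)
        if np.isfinite(f_new) and f_new <= f + 1e-12:
            protos, W_bases, f = protos_new, W_new, f_new
        if not np.isfinite(f_new):
            raise FloatingPointError(f"fit diverged at iteration {it} (parameter block)")

        bank = TensorBank(protos)
        # block 2: embeddings
        if k > 1:
            z_new = [
                _update_embedding(tr, S, z, bank, W_bases, cfg, activation)
                for tr, S, z in zip(trajs, S_list, z_list)
            ]
            f_new = objective(protos, W_bases, z_new, S_list)
            if np.isfinite(f_new) and f_new <= f + 1e-12:
                z_list, f = z_new, f_new

        # block 3: latent paths
        S_new = []
        for tr, S, z in zip(trajs, S_list, z_list):
            W = np.tensordot(z.z, W_bases, axes=(0, 0))
            T_p = build_patient_tensor(z, bank)
            if activation == "identity":
                cand = _solve_quadratic_path(tr, W, np.eye(q), T_p,
                                             cfg.consistency_weight, cfg.smooth_weight)
            else:
                cand = infer_latents(
                    tr, z,
                    LatentDynamicsModel(
                        bank=bank,
                        emission=EmissionModel(
                            W_bases, np.broadcast_to(np.eye(q), (k, q, q)).copy()
                        ),
                        layout=layout, activation=activation,
                    ),
                    smooth_weight=cfg.consistency_weight,
                    step_weight=cfg.smooth_weight,
                    max_iters=20, init=S,
                )
            args = (tr, W, np.eye(q), T_p, activation,
                    cfg.consistency_weight, cfg.smooth_weight)
            S_new.append(cand if _path_objective(cand, *args) <=
                         _path_objective(S, *args) else S)
        f_new = objective(protos, W_bases, z_list, S_new)
        if np.isfinite(f_new) and f_new <= f + 1e-12:
            S_list, f = S_new, f_new

        trace.append(f)
        if len(trace) >= 2 and trace[-2] - trace[-1] <= cfg.tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    # residual variance -> isotropic emission covariances for the checkpoint
    resid_ss, n_obs_vals = 0.0, 0
    for tr, S, z in zip(trajs, S_list, z_list):
        W = np.tensordot(z.z, W_bases, axes=(0, 0))
        resid_ss += float(np.sum((tr.observations - S @ W.T) ** 2))
        n_obs_vals += tr.observations.size
    sigma2 = resid_ss / max(n_obs_vals, 1)
    sigmas = np.broadcast_to(sigma2 * np.eye(q), (k, q, q)).copy()

    model = LatentDynamicsModel(
        bank=TensorBank(protos),
        emission=EmissionModel(W_bases, sigmas),
        layout=layout,
        activation=activation,
    )
    return FitResult(
        model=model,
        embeddings=z_list,
        latents=S_list,
        objective_trace=np.asarray(trace),
        converged=converged,
    )


# ---------------------------------------------------------------- evaluation


def predictive_mse(
    model: LatentDynamicsModel,
    embeddings: Sequence[PatientEmbedding],
    heldout: Sequence[Trajectory],
) -> float:
    """Mean squared one-step-ahead observation prediction error.

    Latents are read off each visit by least squares against the patient's
    read-out matrix; the next visit's observation is predicted through the
    dynamics.  The mean runs over patients, transitions, and coordinates.
    """
    sigma = get_activation(model.activation)
    bank = model.dense_bank()
    total, n = 0.0, 0
    for z, tr in zip(embeddings, heldout):
        W, _ = patient_emission_params(z, model.emission)
        T_p = build_patient_tensor(z, bank)
        S_hat = np.linalg.lstsq(W, tr.observations.T, rcond=None)[0].T
        for t in range(tr.T - 1):
            pred = W @ sigma(T_p[:, :, int(tr.actions[t])] @ S_hat[t])
            total += float(np.sum((tr.observations[t + 1] - pred) ** 2))
            n += tr.observations.shape[1]
    return total / max(n, 1)
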