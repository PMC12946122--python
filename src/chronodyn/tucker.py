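"""Tucker decomposition of small dense tensors via higher-order SVD.

Kolda & Bader conventions: ``unfold(X, n)`` arranges mode-n fibers as
columns; ``mode_dot(X, U, n)`` is the mode-n product X ×_n U.  The
decomposition is truncated HOSVD optionally refined by HOOI (orthogonal
iteration), which never increases the reconstruction error of its HOSVD
initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TuckerFactors", "mode_dot", "unfold", "tucker_reconstruct", "tucker_decompose"]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: shape (I_n, prod of other dims)."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(matrix.reshape(full), 0, mode)


def mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product X ×_n U (U has shape (J, I_n))."""
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"mode-{mode} product: matrix columns {matrix.shape[1]} "
            f"!= tensor dim {tensor.shape[mode]}"
        )
    new_shape = list(tensor.shape)
    new_shape[mode] = matrix.shape[0]
    return fold(matrix @ unfold(tensor, mode), mode, tuple(new_shape))


@dataclass(frozen=True)
class TuckerFactors:
    """Core tensor plus one orthonormal-column factor matrix per mode."""

    core: np.ndarray
    factors: tuple

    def __post_init__(self):
        core = np.asarray(self.core, dtype=float)
        factors = tuple(np.asarray(u, dtype=float) for u in self.factors)
        object.__setattr__(self, "core", core)
        object.__setattr__(self, "factors", factors)
        if core.ndim != len(factors):
            raise ValueError("need one factor matrix per core mode")
        for n, u in enumerate(factors):
            if u.ndim != 2 or u.shape[1] != core.shape[n]:
                raise ValueError(
                    f"factor {n} shape {u.shape} incompatible with core dim {core.shape[n]}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(u.shape[0] for u in self.factors)

    @property
    def ranks(self) -> tuple[int, ...]:
        return self.core.shape


def tucker_reconstruct(f: TuckerFactors) -> np.ndarray:
    """G ×_1 U_1 ×_2 U_2 ... — the full tensor implied by the factors."""
    out = f.core
    for n, u in enumerate(f.factors):
        out = mode_dot(out, u, n)
    return out


def _hosvd_factors(tensor: np.ndarray, ranks: tuple[int, ...]) -> list[np.ndarray]:
    factors = []
    for n, r in enumerate(ranks):
        u, _, _ = np.linalg.svd(unfold(tensor, n), full_matrices=False)
        factors.append(u[:, :r])
    return factors


def tucker_decompose(
    tensor: np.ndarray, ranks: tuple[int, ...], n_iter: int = 10, tol: float = 1e-12
) -> TuckerFactors:
    """Truncated HOSVD refined by HOOI.

    At full ranks the result reproduces the tensor to machine precision; at
    reduced ranks the reconstruction error is never worse than plain
    truncated HOSVD (HOOI starts there and is monotone).  Factor matrices
    have orthonormal columns.
    """
    tensor = np.asarray(tensor, dtype=float)
    if len(ranks) != tensor.ndim:
        raise ValueError(f"need {tensor.ndim} ranks, got {len(ranks)}")
    for n, r in enumerate(ranks):
        if not (1 <= r <= tensor.shape[n]):
            raise ValueError(f"rank {r} invalid for mode {n} of size {tensor.shape[n]}")

    factors = _hosvd_factors(tensor, tuple(ranks))
    norm = np.linalg.norm(tensor)

    def core_of(fs):
        g = tensor
        for n, u in enumerate(fs):
            g = mode_dot(g, u.T, n)
        return g

    prev_fit = np.linalg.norm(core_of(factors))
    for _ in range(n_iter):
        for n in range(tensor.ndim):
            # project out every mode but n, then take leading left singular vectors
            y = tensor
            for j, u in enumerate(factors):
                if j != n:
                    y = mode_dot(y, u.T, j)
            u, _, _ = np.linalg.svd(unfold(y, n), full_matrices=False)
            factors[n] = u[:, : ranks[n]]
        fit = np.linalg.norm(core_of(factors))
        if abs(fit - prev_fit) <= tol * max(norm, 1.0):
            break
        prev_fit = fit
    return TuckerFactors(core=core_of(factors), factors=tuple(factors))
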