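"""The two objectives: cross-entropy and sparse group lasso.

f1 is the mean cross-entropy of the softmax posterior. f2 is a sparse
group lasso over the connection groups: per group, the group dimension
times its Euclidean norm (zeroing whole neurons), plus an elementwise L1
term over all weights and biases (zeroing individual connections). The
group coefficient defaults to the dimension ``#g``; the classical
``sqrt(#g)`` weighting is available via ``group_weight="sqrt_dim"``.

Because the two objectives live on very different scales, the trainer
works with normalized values: during initialization F is divided by its
own Euclidean norm, during training by the per-objective magnitudes
captured at the end of initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bfselect.mlp_core import NetworkParams, forward

__all__ = [
    "ObjectiveState",
    "cross_entropy",
    "cross_entropy_gradient",
    "sparse_group_lasso",
    "sparse_group_lasso_gradient",
    "objective_vector",
    "objective_gradients",
    "normalize_init",
    "normalize_train",
]

LOG_FLOOR = 1e-12
REF_FLOOR = 1e-12


@dataclass
class ObjectiveState:
    """Biobjective vector F = (f1, f2), raw and normalized, with flat
    gradients aligned to the NetworkParams flattening."""

    f_raw: tuple[float, float]
    f_norm: tuple[float, float] | None = None
    grads: tuple[np.ndarray, np.ndarray] | None = None
    norm_refs: tuple[float, float] | None = None


def _group_coeff(dim: int, group_weight: str) -> float:
    if group_weight == "dim":
        return float(dim)
    if group_weight == "sqrt_dim":
        return float(np.sqrt(dim))
    raise ValueError(f"unknown group_weight {group_weight!r}")


def cross_entropy(params: NetworkParams, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean over samples of −Σ_k Y_ik log Ŷ_ik, log arguments floored at
    1e−12 so saturated softmax outputs stay finite."""
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    probs = forward(params, X)
    return float(-np.sum(Y * np.log(np.maximum(probs, LOG_FLOOR))) / X.shape[0])


def cross_entropy_gradient(params: NetworkParams, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Flat gradient of the cross-entropy by backpropagation.

    Softmax + cross-entropy collapse to the output delta (P − Y)/N;
    hidden deltas gate through the ReLU mask.
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    probs, acts = forward(params, X, return_hidden=True)
    n = X.shape[0]
    L = params.spec.n_layers
    delta = (probs - Y) / n
    grads_w = [None] * L
    grads_b = [None] * L
    for l in range(L - 1, -1, -1):
        grads_w[l] = acts[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ params.weights[l].T) * (acts[l] > 0)
    parts = []
    for gw, gb in zip(grads_w, grads_b):
        parts.append(gw.ravel())
        parts.append(gb)
    return np.concatenate(parts)


def sparse_group_lasso(params: NetworkParams, group_weight: str = "dim") -> float:
    """Σ_g c(#g)·‖g‖₂ over all connection groups plus the L1 norm of all
    weights and biases; zero iff every parameter is zero."""
    total = 0.0
    for l, w in enumerate(params.weights):
        dim = w.shape[1]
        coeff = _group_coeff(dim, group_weight)
        total += coeff * float(np.linalg.norm(w, axis=1).sum())
        total += float(np.abs(w).sum())
    for b in params.biases:
        total += float(np.abs(b).sum())
    return total


def sparse_group_lasso_gradient(params: NetworkParams, group_weight: str = "dim") -> np.ndarray:
    """Flat subgradient of the sparse group lasso.

    Per group g: c(#g)·g/‖g‖₂, taken as 0 for a zero group; the L1 part
    contributes sign(θ) with sign(0) = 0 (the minimum-norm subgradient,
    so parameters already at zero feel no regularizer pull).
    """
    parts = []
    for w, b in zip(params.weights, params.biases):
        coeff = _group_coeff(w.shape[1], group_weight)
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            gw = np.where(norms > 0, coeff * w / np.where(norms > 0, norms, 1.0), 0.0)
        gw = gw + np.sign(w)
        parts.append(gw.ravel())
        parts.append(np.sign(b))
    return np.concatenate(parts)


def objective_vector(
    params: NetworkParams, X: np.ndarray, Y: np.ndarray, group_weight: str = "dim"
) -> ObjectiveState:
    return ObjectiveState(
        f_raw=(cross_entropy(params, X, Y), sparse_group_lasso(params, group_weight))
    )


def objective_gradients(
    params: NetworkParams,
    X: np.ndarray,
    Y: np.ndarray,
    group_weight: str = "dim",
    scales: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Flat gradients (∇f1, ∇f2), each divided by its normalization
    scale (the scales are treated as constants of the current iteration)."""
    g1 = cross_entropy_gradient(params, X, Y) / scales[0]
    g2 = sparse_group_lasso_gradient(params, group_weight) / scales[1]
    return g1, g2


def normalize_init(F: tuple[float, float]) -> tuple[float, float]:
    """Initialization-phase normalization: F / ‖F‖₂ (unit norm output)."""
    norm = float(np.hypot(F[0], F[1]))
    if norm == 0.0:
        raise ValueError("degenerate objective vector (0, 0)")
    return (F[0] / norm, F[1] / norm)


def normalize_train(F: tuple[float, float], refs: tuple[float, float]) -> tuple[float, float]:
    """Training-phase normalization: divide each objective by the
    reference magnitude captured at the end of initialization."""
    r1 = max(abs(refs[0]), REF_FLOOR)
    r2 = max(abs(refs[1]), REF_FLOOR)
    return (F[0] / r1, F[1] / r2)
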