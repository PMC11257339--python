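"""Direction-finding subproblems.

Training steps move along the min-norm element of the convex hull of the
(normalized) objective gradients and the gradient of any active region
constraint. The primal program

    min_{d, γ}  γ + ½‖d‖²   s.t.  g_i·d ≤ γ for every gradient g_i

has the dual: maximize −½‖Σ w_i g_i‖² over the probability simplex, with
d* = −Σ w_i g_i. The dual involves only the |grads|×|grads| Gram matrix,
so its cost is independent of the parameter count — with two objectives
and at most one active constraint there are never more than a handful of
gradients. We solve it exactly by enumerating the faces of the simplex:
for each non-empty support, the equality-constrained minimizer follows
from one small linear solve; the best feasible candidate is the global
optimum of this convex QP.

The initialization subproblem restricted to the active constraint
gradient alone has the closed form d0 = −∇G, γ0 = −‖∇G‖².
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "DescentSolution",
    "solve_init_direction",
    "solve_dual",
    "training_direction",
    "mgda_direction",
]

STATIONARY_TOL = 1e-6
_GRAM_RIDGE = 1e-12


@dataclass
class DescentSolution:
    """Descent direction with its dual certificate.

    ``weights`` are the simplex multipliers over all supplied gradients;
    ``lambdas``/``betas`` split them by origin (objectives vs active
    constraints). ``combined_norm`` is ‖Σ w_i g_i‖₂; a value below the
    stationarity tolerance signals a Pareto-stationary point.
    """

    direction: np.ndarray
    gamma: float
    weights: np.ndarray
    lambdas: np.ndarray
    betas: np.ndarray
    combined_norm: float

    @property
    def is_stationary(self) -> bool:
        return self.combined_norm < STATIONARY_TOL


def solve_init_direction(constraint_grads: list[np.ndarray]) -> DescentSolution:
    """Initialization direction: steepest descent on the single active
    region constraint; the zero direction when no constraint is active."""
    if len(constraint_grads) == 0:
        z = np.zeros(0)
        return DescentSolution(z, 0.0, np.zeros(0), np.zeros(0), np.zeros(0), 0.0)
    if len(constraint_grads) > 1:
        raise ValueError("at most one active constraint expected")
    g = np.asarray(constraint_grads[0], dtype=np.float64)
    nrm = float(np.linalg.norm(g))
    return DescentSolution(
        direction=-g,
        gamma=-(nrm**2),
        weights=np.ones(1),
        lambdas=np.zeros(0),
        betas=np.ones(1),
        combined_norm=nrm,
    )


def _min_norm_weights(gram: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact min of wᵀGw over the probability simplex by support
    enumeration; returns (weights, objective value)."""
    m = gram.shape[0]
    best_w, best_val = None, np.inf
    ridge = _GRAM_RIDGE * np.eye(m)
    G = gram + ridge
    ones = np.ones(m)
    for size in range(1, m + 1):
        for support in combinations(range(m), size):
            idx = list(support)
            Gs = G[np.ix_(idx, idx)]
            # KKT on the face: Gs w = μ·1, 1ᵀw = 1  →  w ∝ Gs⁻¹1
            try:
                sol = np.linalg.solve(Gs, ones[: len(idx)])
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(Gs, ones[: len(idx)], rcond=None)
            s = sol.sum()
            if abs(s) < 1e-300:
                continue
            w_face = sol / s
            if np.any(w_face < -1e-9):
                continue
            w = np.zeros(m)
            w[idx] = np.clip(w_face, 0.0, None)
            w /= w.sum()
            val = float(w @ gram @ w)
            if val < best_val - 1e-15:
                best_val, best_w = val, w
    return best_w, max(best_val, 0.0)


def solve_dual(grads: list[np.ndarray]) -> DescentSolution:
    """Min-norm point of the convex hull of the given gradients, via the
    dual QP on the Gram matrix."""
    if len(grads) == 0:
        raise ValueError("need at least one gradient")
    G = np.stack([np.asarray(g, dtype=np.float64) for g in grads])
    if G.ndim != 2:
        raise ValueError("gradients must be flat vectors of equal length")
    gram = G @ G.T
    w, val = _min_norm_weights(gram)
    d = -(w @ G)
    combined = float(np.sqrt(val))
    if combined < STATIONARY_TOL:
        d = np.zeros_like(d)
    # γ* = max_i g_i·d at the optimum (= −‖d‖² when all weights interior)
    gamma = float(np.max(G @ d)) if combined >= STATIONARY_TOL else 0.0
    return DescentSolution(
        direction=d,
        gamma=gamma,
        weights=w,
        lambdas=w,
        betas=np.zeros(0),
        combined_norm=combined,
    )


def training_direction(
    obj_grads: list[np.ndarray], active_constraint_grads: list[np.ndarray] | None = None
) -> DescentSolution:
    """Constrained descent direction: min-norm point over the objective
    gradients plus the active region-constraint gradient (if any)."""
    if len(obj_grads) != 2:
        raise ValueError("expected exactly two objective gradients")
    cgrads = list(active_constraint_grads or [])
    sol = solve_dual(list(obj_grads) + cgrads)
    sol.lambdas = sol.weights[:2]
    sol.betas = sol.weights[2:]
    return sol


def mgda_direction(obj_grads: list[np.ndarray]) -> DescentSolution:
    """Unconstrained min-norm biobjective direction (the multiple
    gradient descent algorithm step); identical to the dual QP with no
    active constraints."""
    if len(obj_grads) != 2:
        raise ValueError("expected exactly two objective gradients")
    return training_direction(obj_grads, [])
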