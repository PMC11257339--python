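"""Two-phase constrained biobjective training, plus the baseline trainers.

For each of the K sectors of the objective plane a fresh network is
trained in two phases (full-batch gradients; every step is taken along
the current descent direction with an Armijo backtracking line search,
the standard step rule for multiobjective steepest descent):

* **Initialization** — the biobjective vector is normalized by its own
  Euclidean norm, and while a region constraint is active the parameters
  move along the steepest-descent direction of that constraint, pulling
  the (normalized) objectives into the sector. The phase ends when the
  sector is reached, when violation progress stalls (at realistic scales
  the raw objectives differ by orders of magnitude and low sectors are
  unreachable — the phase then exits "as close as possible"), or after
  ``init_fraction`` of the epoch budget. The raw objective magnitudes at
  exit become the training-phase normalization references.

* **Training** — objectives are normalized by those references. While
  the point sits outside its sector (a constraint is violated beyond the
  ε band) the epoch is a *restoration* step: single-objective descent of
  the objective whose decrease moves the point toward the sector — the
  sparsity term when the point lies above the sector, the loss when it
  lies below. Restoration trades the other objective freely, which is
  what lets a network actually reach a low-sparsity sector; a common
  descent direction cannot, since leaving the overfitted loss minimum
  requires the loss to rise. Once (ε-near) feasible, each epoch steps
  along the min-norm direction over the two objective gradients plus the
  gradient of any active sector constraint (the dual QP). Stops at the
  epoch budget, after ``patience`` epochs without improvement of the
  summed normalized objectives, or at a Pareto-stationary point.

Baselines: ``l1`` and ``sgl`` are single-objective scalarizations
(cross-entropy + weight·penalty) under plain gradient descent;
``moo_mtl`` is the unconstrained min-norm biobjective method; and
``bfs_init_only`` keeps the sector-seeking initialization but trains
unconstrained. The unconstrained variants normalize by the objective
magnitudes at the start of their training phase, the same rule the
constrained trainer applies at the initialization/training hand-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bfselect.mlp_core import Dataset, NetworkParams, NetworkSpec, init_network
from bfselect.objectives import (
    REF_FLOOR,
    cross_entropy,
    cross_entropy_gradient,
    normalize_init,
    normalize_train,
    sparse_group_lasso,
    sparse_group_lasso_gradient,
)
from bfselect.regions import DEFAULT_EPSILON, RegionSet, active_set, build_regions, constraint_values
from bfselect.descent_solver import (
    mgda_direction,
    solve_init_direction,
    training_direction,
)

__all__ = ["TrainerConfig", "TrainingRecord", "run_init_step", "run_training_step", "train_bfs", "train_baseline"]

IMPROVEMENT_TOL = 1e-6
METHODS = ("bfs", "bfs_init_only", "moo_mtl", "l1", "sgl")

# Armijo backtracking: accept θ + t·d once every tracked quantity has
# decreased by at least ARMIJO_SIGMA · t · (its guaranteed linear rate)
ARMIJO_SIGMA = 1e-4
ARMIJO_SHRINK = 0.5
ARMIJO_MAX_HALVINGS = 30

# the initialization phase stops once constraint-violation progress per
# epoch falls below this (the sector is unreachable at this scale)
INIT_STALL_TOL = 1e-8
INIT_STALL_EPOCHS = 3


def _armijo_step(params: NetworkParams, direction, t0, values, rates, evaluate):
    """Backtracking line search along ``direction``.

    ``values`` are the current tracked quantities, ``rates`` their
    directional derivatives along the step (all negative for a descent
    direction), and ``evaluate()`` recomputes them at the trial point.
    Returns the accepted step length (0.0 if the search failed; params
    are restored in that case).
    """
    t = t0
    for _ in range(ARMIJO_MAX_HALVINGS):
        params.add_flat(t * direction)
        trial = evaluate()
        ok = all(v_new <= v + ARMIJO_SIGMA * t * r
                 for v_new, v, r in zip(trial, values, rates))
        if ok:
            return t
        params.add_flat(-t * direction)
        t *= ARMIJO_SHRINK
    return 0.0


@dataclass
class TrainerConfig:
    """Hyperparameters shared by the constrained trainer and baselines."""

    K_regions: int = 10
    max_epochs: int = 1000
    init_fraction: float = 0.2
    patience: int = 10
    learning_rate: float = 1.0  # initial Armijo trial step
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    method: str = "bfs"
    scalarization_weight: float = 1e-2
    hidden_layers: tuple[int, ...] = (100,)
    group_weight: str = "dim"
    # explicit initialization budget; None derives it as
    # ceil(init_fraction * max_epochs)
    init_epochs: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.init_fraction < 1.0):
            raise ValueError("init_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.K_regions < 1:
            raise ValueError("K_regions must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


@dataclass
class TrainingRecord:
    """Per-epoch history of one network's run."""

    region: int
    f_raw: list[tuple[float, float]] = field(default_factory=list)
    f_norm: list[tuple[float, float]] = field(default_factory=list)
    active: list[list[int]] = field(default_factory=list)
    step_norm: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)
    norm_refs: tuple[float, float] | None = None
    stop_reason_init: str | None = None
    stop_reason_train: str | None = None

    def log(self, phase, f_raw, f_norm, act, step):
        self.phase.append(phase)
        self.f_raw.append(f_raw)
        self.f_norm.append(f_norm)
        self.active.append(list(act))
        self.step_norm.append(step)


def _objectives(params: NetworkParams, data: Dataset, group_weight: str) -> tuple[float, float]:
    return (
        cross_entropy(params, data.X_train, data.Y_train),
        sparse_group_lasso(params, group_weight),
    )


def _constraint_gradient(j: int, regions: RegionSet, k: int, g1n, g2n) -> np.ndarray:
    """Gradient of G1 = −F̂·z_k or G2 = F̂·z_{k+1} given the normalized
    objective gradients (the normalization scale is held constant)."""
    if j == 1:
        z = regions.normals[k - 1]
        return -(z[0] * g1n + z[1] * g2n)
    z = regions.normals[k]
    return z[0] * g1n + z[1] * g2n


def run_init_step(
    params: NetworkParams,
    k: int,
    regions: RegionSet,
    data: Dataset,
    config: TrainerConfig,
    record: TrainingRecord | None = None,
) -> tuple[tuple[float, float], TrainingRecord]:
    """Sector-seeking initialization (in place on ``params``).

    Returns the normalization references (|f1|, |f2| at exit, floored)
    and the record. Capped at ceil(init_fraction · max_epochs) epochs.
    """
    record = record if record is not None else TrainingRecord(region=k)
    budget = (config.init_epochs if config.init_epochs is not None
              else int(np.ceil(config.init_fraction * config.max_epochs)))
    F = _objectives(params, data, config.group_weight)
    stalled = 0

    for _ in range(budget):
        Fn = normalize_init(F)
        cs = constraint_values(Fn, regions, k)
        act = active_set(cs, config.epsilon)
        if not act:
            record.log("init", F, Fn, act, 0.0)
            record.stop_reason_init = "in_region"
            break
        j = act[0]
        scale = float(np.hypot(*F))
        g1n = cross_entropy_gradient(params, data.X_train, data.Y_train) / scale
        g2n = sparse_group_lasso_gradient(params, config.group_weight) / scale
        grad_c = _constraint_gradient(j, regions, k, g1n, g2n)
        sol = solve_init_direction([grad_c])
        if sol.is_stationary:
            record.log("init", F, Fn, act, 0.0)
            record.stop_reason_init = "stationary"
            break

        trial_F = [F]

        def _eval():
            trial_F[0] = _objectives(params, data, config.group_weight)
            return [constraint_values(normalize_init(trial_F[0]), regions, k)[j - 1]]

        t = _armijo_step(
            params, sol.direction, config.learning_rate,
            [cs[j - 1]], [float(grad_c @ sol.direction)], _eval,
        )
        record.log("init", F, Fn, act, t * float(np.linalg.norm(sol.direction)))
        if t == 0.0:
            record.stop_reason_init = "line_search"
            break
        new_violation = constraint_values(normalize_init(trial_F[0]), regions, k)[j - 1]
        if cs[j - 1] - new_violation < INIT_STALL_TOL:
            stalled += 1
            if stalled >= INIT_STALL_EPOCHS:
                F = trial_F[0]
                record.stop_reason_init = "stalled"
                break
        else:
            stalled = 0
        F = trial_F[0]
    else:
        record.stop_reason_init = "init_budget"
    if not record.phase:  # zero budget edge: still record the state
        record.log("init", F, normalize_init(F), [], 0.0)
        record.stop_reason_init = "in_region"
    refs = (max(abs(F[0]), REF_FLOOR), max(abs(F[1]), REF_FLOOR))
    record.norm_refs = refs
    return refs, record


def run_training_step(
    params: NetworkParams,
    k: int,
    regions: RegionSet,
    data: Dataset,
    config: TrainerConfig,
    norm_refs: tuple[float, float],
    record: TrainingRecord | None = None,
    constrained: bool = True,
) -> TrainingRecord:
    """Constrained min-norm biobjective descent (in place on ``params``).

    With ``constrained=False`` the sector constraints are ignored — this
    is the unconstrained (MGDA) training used by the baselines.
    """
    if norm_refs[0] <= 0 or norm_refs[1] <= 0:
        raise ValueError("normalization references must be positive")
    record = record if record is not None else TrainingRecord(region=k, norm_refs=norm_refs)
    best = np.inf
    stall = 0
    F = _objectives(params, data, config.group_weight)
    for _ in range(config.max_epochs):
        Fn = normalize_train(F, norm_refs)
        g1n = cross_entropy_gradient(params, data.X_train, data.Y_train) / norm_refs[0]
        g2n = sparse_group_lasso_gradient(params, config.group_weight) / norm_refs[1]
        if constrained:
            cs = constraint_values(Fn, regions, k)
            act = active_set(cs, config.epsilon)
            violated = [j for j in act if cs[j - 1] > config.epsilon]
        else:
            cs = None
            act = []
            violated = []

        trial_F = [F]
        if violated:
            # restoration: G1 violated means the point lies below the
            # sector (loss too high relative to sparsity) — descend f̂1;
            # G2 violated means it lies above — descend f̂2
            j = violated[0]
            g = g1n if j == 1 else g2n
            obj_i = j - 1

            def _eval_restore():
                trial_F[0] = _objectives(params, data, config.group_weight)
                return [normalize_train(trial_F[0], norm_refs)[obj_i]]

            t = _armijo_step(
                params, -g, config.learning_rate,
                [Fn[obj_i]], [-float(g @ g)], _eval_restore,
            )
            step = t * float(np.linalg.norm(g))
        else:
            sol = training_direction([g1n, g2n],
                                     [_constraint_gradient(j, regions, k, g1n, g2n)
                                      for j in act]) if constrained else mgda_direction([g1n, g2n])
            if sol.is_stationary:
                record.log("train", F, Fn, act, 0.0)
                record.stop_reason_train = "stationary"
                return record

            # Armijo on both normalized objectives and any active
            # constraint, each against the dual certificate γ* = max g_i·d
            values = [Fn[0], Fn[1]] + [cs[j - 1] for j in act]

            def _eval():
                trial_F[0] = _objectives(params, data, config.group_weight)
                fn = normalize_train(trial_F[0], norm_refs)
                out = [fn[0], fn[1]]
                if act:
                    trial_cs = constraint_values(fn, regions, k)
                    out += [trial_cs[j - 1] for j in act]
                return out

            t = _armijo_step(
                params, sol.direction, config.learning_rate, values,
                [sol.gamma] * len(values), _eval,
            )
            step = t * float(np.linalg.norm(sol.direction))

        record.log("train", F, Fn, act, step)
        if t == 0.0:
            record.stop_reason_train = "line_search"
            return record
        F = trial_F[0]
        Fn_new = normalize_train(F, norm_refs)
        value = Fn_new[0] + Fn_new[1]
        if value < best - IMPROVEMENT_TOL:
            best = value
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                record.stop_reason_train = "patience"
                return record
    record.stop_reason_train = "max_epochs"
    return record


def _fresh_network(data: Dataset, config: TrainerConfig, k: int) -> NetworkParams:
    spec = NetworkSpec(
        (data.n_features, *config.hidden_layers, data.n_classes), seed=config.seed + k
    )
    return init_network(spec)


def train_bfs(data: Dataset, config: TrainerConfig) -> list[tuple[NetworkParams, TrainingRecord]]:
    """Run the full two-phase procedure for every sector k = 1..K.

    Returns K (params, record) pairs; network k was confined to sector k
    and seeded with config.seed + k, so the run is reproducible and the
    sectors are independent.
    """
    regions = build_regions(config.K_regions)
    out = []
    for k in range(1, config.K_regions + 1):
        params = _fresh_network(data, config, k)
        record = TrainingRecord(region=k)
        refs, record = run_init_step(params, k, regions, data, config, record)
        run_training_step(params, k, regions, data, config, refs, record, constrained=True)
        out.append((params, record))
    return out


BASELINE_STEP = 0.1


def _train_scalarized(data: Dataset, config: TrainerConfig, k: int, penalty: str):
    """Plain fixed-step gradient descent on cross-entropy + weight·penalty.

    The scalarized baselines deliberately keep the classical fixed step
    (``BASELINE_STEP``) rather than the line search: their subgradient
    dynamics then oscillate around zero with an amplitude above the
    sparsity-counting threshold, which is the canonical behavior of
    L1-regularized gradient descent at these scales.
    """
    params = _fresh_network(data, config, k)
    record = TrainingRecord(region=k)
    w = config.scalarization_weight
    best = np.inf
    stall = 0

    def _l1_value(p):
        return float(sum(np.abs(m).sum() for m in p.weights) + sum(np.abs(b).sum() for b in p.biases))

    for _ in range(config.max_epochs):
        F = _objectives(params, data, config.group_weight)
        if penalty == "l1":
            reg = _l1_value(params)
            reg_grad_parts = []
            for m, b in zip(params.weights, params.biases):
                reg_grad_parts.append(np.sign(m).ravel())
                reg_grad_parts.append(np.sign(b))
            reg_grad = np.concatenate(reg_grad_parts)
        else:  # sparse group lasso
            reg = F[1]
            reg_grad = sparse_group_lasso_gradient(params, config.group_weight)
        loss = F[0] + w * reg
        grad = cross_entropy_gradient(params, data.X_train, data.Y_train) + w * reg_grad
        record.log("train", F, (loss, w * reg), [], BASELINE_STEP * float(np.linalg.norm(grad)))
        if loss < best - IMPROVEMENT_TOL:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                record.stop_reason_train = "patience"
                return params, record
        params.add_flat(-BASELINE_STEP * grad)
    record.stop_reason_train = "max_epochs"
    return params, record


def train_baseline(data: Dataset, config: TrainerConfig) -> list[tuple[NetworkParams, TrainingRecord]]:
    """Train one of the comparison methods.

    Each method returns ``K_regions`` networks (one repetition per
    region index) so population-level comparisons against the
    constrained trainer are like-for-like.
    """
    regions = build_regions(config.K_regions)
    out = []
    for k in range(1, config.K_regions + 1):
        if config.method in ("l1", "sgl"):
            out.append(_train_scalarized(data, config, k, config.method))
            continue
        params = _fresh_network(data, config, k)
        record = TrainingRecord(region=k)
        if config.method == "bfs_init_only":
            refs, record = run_init_step(params, k, regions, data, config, record)
        elif config.method == "moo_mtl":
            F = _objectives(params, data, config.group_weight)
            refs = (max(abs(F[0]), REF_FLOOR), max(abs(F[1]), REF_FLOOR))
            record.norm_refs = refs
        else:
            raise ValueError(f"unknown baseline method {config.method!r}")
        run_training_step(params, k, regions, data, config, refs, record, constrained=False)
        out.append((params, record))
    return out
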