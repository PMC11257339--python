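# Methods

## Problem setting

High-dimension low-sample-size (HDLSS) classification: a feature matrix
with p features and n ≪ p training samples (the bundled benchmarks use
n = 900 against p = 2000–3000). A multilayer perceptron trained by
maximum likelihood in this regime overfits: noise features acquire
weight because they help memorize the training set. The package embeds
feature selection into training by treating sparsity as a second
objective rather than a penalty with a hand-tuned weight, and returns a
*population* of networks spanning the accuracy–sparsity trade-off.

## Objectives

For an MLP with ReLU hidden layers and softmax output,

* **f₁ — cross-entropy.** Mean over samples of −Σₖ Yᵢₖ log Ŷᵢₖ, with
  log arguments floored at 1e−12.
* **f₂ — sparse group lasso.** Connection *groups* are the outgoing
  weight vectors of each input and hidden neuron (rows of the weight
  matrices). f₂ = Σ_g c(#g)·‖g‖₂ + Σ‖θᵢˡ‖₁, where the L1 part runs over
  all weights and biases. Zeroing an input neuron's group removes that
  feature. The group coefficient c defaults to the group dimension #g; a
  `group_weight="sqrt_dim"` switch selects the classical √#g weighting.
  The subgradient uses the minimum-norm element at kinks (zero group →
  zero vector; sign(0) = 0), so parameters already at zero feel no
  regularizer pull.

f₂ is positively homogeneous of degree 1 and satisfies Euler's relation
∇f₂·θ = f₂ away from kinks; both properties are tested.

## Sector geometry

The positive quadrant of normalized objective space is split into K
evenly spaced angular sectors. Sector k is delimited by rays at angles
φ_k, φ_{k+1} (φ spanning [0, π/2]) with unit normals
z_k = (−sin φ_k, cos φ_k); membership is the pair of linear constraints
G1 = −F̂·z_k ≤ 0 and G2 = F̂·z_{k+1} ≤ 0. Only these two constraints
enter the subproblem regardless of K. A constraint is *active* when its
value exceeds −ε (default ε = 1e−3; if both qualify the more violated
one is kept, which the sector geometry otherwise guarantees).

## Direction finding

The direction subproblem min_{d,γ} γ + ½‖d‖² s.t. gᵢ·d ≤ γ over the
objective gradients and any active constraint gradient is solved through
its dual: minimize ‖Σ wᵢ gᵢ‖² over the probability simplex, d★ = −Σ wᵢ gᵢ.
The dual touches only the Gram matrix (at most 3×3 here), so its cost is
independent of the parameter count. With ≤ 4 gradients we solve it
*exactly* by enumerating simplex faces: each support yields one linear
solve (Gw ∝ 1 on the face); the best feasible candidate is the global
optimum of this convex QP. A 1e−12 ridge guards rank-deficient Gram
matrices; a combined norm below 1e−6 is treated as Pareto stationarity.

## Two-phase training

Every phase normalizes the objectives, because their raw scales differ
by four orders of magnitude (cross-entropy ≈ 0.7, sparse group lasso
≈ 3·10⁴ at initialization for the benchmark networks).

**Initialization** (budget: 20 % of the epoch limit) normalizes F by its
own Euclidean norm and, while a sector constraint is active, descends
that constraint's gradient. On O(1)-scale problems this disperses the
population across sectors before training. At benchmark scale the
‖F‖-normalization cannot make low sectors reachable (the normalized
point is pinned near the f₂ axis; analysis showed the violation decrease
per epoch collapses), so the phase detects the stall (< 1e−8 progress
for 3 epochs) and exits "as close as possible". The raw |f₁|, |f₂| at
exit become the training references.

**Training** normalizes by those references (so the phase starts at
(1, 1) in normalized coordinates) and alternates two step types:

* *Restoration* — while a sector constraint is violated beyond ε, the
  epoch descends the single objective whose decrease moves the point
  toward the sector: the sparsity term when the point lies above its
  sector, the loss when below. This step intentionally trades the other
  objective; without it a network can never enter a low-angle sector,
  because leaving the loss minimum requires the loss to rise and a
  common descent direction forbids that.
* *Constrained min-norm descent* — once ε-feasible, the epoch steps
  along the dual-QP direction over both objective gradients plus any
  ε-active constraint gradient, which descends every component
  simultaneously.

Steps use an Armijo backtracking line search (initial step 1.0, σ =
1e−4, halving, ≤ 30 halvings) against the dual certificate γ★ — the
standard step rule for multiobjective steepest descent. Stopping:
epoch limit (default 1000), Pareto stationarity, line-search failure, or
no improvement of the summed normalized objectives by > 1e−6 for
`patience` (default 10) consecutive epochs.

With K = 1 the sector covers the whole quadrant, no constraint ever
activates, and the trainer is bit-identical to unconstrained min-norm
biobjective descent — a tested invariant.

## Baselines

* **moo_mtl** — unconstrained min-norm biobjective descent; references
  taken at training start.
* **bfs_init_only** — sector-seeking initialization, then unconstrained
  training.
* **l1 / sgl** — scalarized cross-entropy + weight·penalty under plain
  *fixed-step* gradient descent (step 0.1, weight default 1e−2). The
  fixed step is deliberate: it is the classical training regime for
  these baselines, and their subgradient dynamics then oscillate around
  zero with amplitude above the 1e−5 sparsity-counting threshold, which
  is why L1-regularized networks score S ≈ 0 despite shrinking weights.
  (Under a line search even plain L1 anneals its steps and parks weights
  below the threshold — an optimizer artifact, not feature selection.)

Each baseline returns one network per region index so population-level
comparisons are like-for-like.

## Evaluation

* **FS score** (informative-features weight ratio): share of input-layer
  L1 mass on the ground-truth informative columns. A fully dead input
  layer returns 0 with a warning.
* **Feature ranking**: importance = ‖g‖₁ per input neuron, ties by index.
* **Sparsity S**: fraction of connection weights with |w| < 1e−5
  (biases excluded).
* **Classification metrics**: accuracy plus support-weighted precision,
  recall, F1 (which coincide with accuracy on balanced, symmetric
  confusion matrices — the behavior seen on the benchmarks).
* **Reporting convention**: per run, classification metrics come from
  the highest-accuracy network; FS and S each from their own maximizing
  network.
* **Filter protocol**: rank features by a trained model, train an
  external classifier trio (random forest / gradient boosting /
  max-margin) on the top-N features for increasing N, report the mean
  test-accuracy curve.
* **Statistical comparison**: per-method Shapiro–Wilk normality
  p-values, then two-sided Wilcoxon signed-rank tests against a control
  method (exact distribution for ≤ 25 nonzero differences). Signed-rank
  (paired) is chosen because compared methods share datasets and seeds.
  All-zero differences are reported as non-comparable rather than forced
  through the test.

## Synthetic data

`generate` builds a balanced dataset with an informative block —
class-specific centroids in a p_informative-dimensional subspace
(orthonormal directions scaled so all centroid pairs sit `class_sep`
apart) plus standard-normal noise — and a label-independent
uniform(0, 1) noise block; columns are shuffled and the informative
positions recorded. Presets: `ad1` (900/2100 split, p = 2000, 50
informative, 2 classes, class_sep 3.8) and `ad2` (900/2100, p = 3000,
100 informative, 3 classes, class_sep 2.9). The separations were
calibrated from the Bayes-ceiling principle: AD1's ceiling is ≈ 0.97 and
AD2's ≈ 0.85 (verified with a logistic oracle on the informative
columns: 0.957 and 0.806), so trained models are limited by how well
they ignore noise columns, and AD2 is harder than AD1 (more classes,
lower informative ratio, smaller separation).

What the generator does *not* emulate: correlated or redundant feature
blocks, heavy-tailed or count-valued features, batch effects, and label
noise. Passing benchmarks therefore demonstrate the selection mechanism
under clean independence assumptions, not robustness to the structure of
real omics data.

**Standardization.** Trainers operate on features centered and scaled by
train-split statistics (`Dataset.standardized()`). This is not cosmetic:
the uniform noise block's DC component otherwise drives every hidden
ReLU unit dead under full-batch descent (verified: 100/100 dead units
and chance accuracy for all methods on raw features).

## Benchmark protocol and problem sizes

`bfselect.experiments.run_benchmark` trains one population per (method,
preset, seed): K = 10 sectors (a reduced sector count — a full sweep
would use ~100), patience 10, one hidden layer of 100 units. The
acceptance script caps training at 500 epochs on `ad1` (with the
initialization budget pinned at its usual 200 epochs via `init_epochs`)
and 400 on `ad2`: populations typically stop on patience after 100–200
epochs, and the caps bound the occasional run that spends hundreds of
line-search epochs in its final stall without moving the population
maxima. The script averages 3 consecutive seeds; the L1 baseline uses 3
repetitions × 300 epochs, ample for its near-zero sparsity measurement.
On one CPU a full population trains in ~1–3 minutes per preset.

## Known limitations

* The sparse extreme on AD2 is weaker than on AD1: with three classes
  and weaker per-column signal, the restoration/descent alternation
  stalls before the noise block is fully dead (population maxima around
  FS ≈ 0.5, S ≈ 0.7 versus ≈ 1.0/0.99 on AD1).
* Sector membership can leak on the low side for small K: once inside
  its sector a network follows the unconstrained Pareto pull, which may
  cross the lower boundary before the ε band reactivates the constraint.
* Fixed architectures only (dense MLP); no mini-batching (all benchmark
  sets are small enough for full-batch gradients).
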