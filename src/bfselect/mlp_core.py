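"""Multilayer perceptron with the connection-group view used for sparsity.

The network is a plain feed-forward MLP: ReLU hidden layers, softmax output.
Parameters are stored per layer as dense float64 arrays; a fixed flattening
order (layer-major; each layer's weight matrix in C order, then its bias)
ties together gradients, the direction-finding QP, and serialization.

The sparsity objective and the feature-selection metrics both act on
*groups*: the vector of all outgoing connection weights of one neuron.
Input-neuron groups are the rows of the first weight matrix; hidden-neuron
groups are the rows of the following weight matrices. Zeroing an input
group removes that feature from the model.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Dataset",
    "NetworkSpec",
    "NetworkParams",
    "GroupStructure",
    "init_network",
    "forward",
    "predict",
    "extract_groups",
    "save_params",
    "load_params",
]

_SERIAL_VERSION = 1


@dataclass
class Dataset:
    """Tabular classification data with one-hot labels and an optional
    set of ground-truth informative feature indices."""

    X_train: np.ndarray
    Y_train: np.ndarray
    X_test: np.ndarray
    Y_test: np.ndarray
    important_idx: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X_train = np.asarray(self.X_train, dtype=np.float64)
        self.X_test = np.asarray(self.X_test, dtype=np.float64)
        self.Y_train = np.asarray(self.Y_train, dtype=np.float64)
        self.Y_test = np.asarray(self.Y_test, dtype=np.float64)
        if self.X_train.shape[0] != self.Y_train.shape[0]:
            raise ValueError("X_train/Y_train row mismatch")
        if self.X_test.shape[0] != self.Y_test.shape[0]:
            raise ValueError("X_test/Y_test row mismatch")
        if self.X_train.shape[1] != self.X_test.shape[1]:
            raise ValueError("train/test feature-count mismatch")
        if self.important_idx is not None:
            self.important_idx = np.asarray(sorted(set(int(i) for i in self.important_idx)))
            if len(self.important_idx) and (
                self.important_idx.min() < 0 or self.important_idx.max() >= self.n_features
            ):
                raise ValueError("important_idx out of range")

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]

    @property
    def n_classes(self) -> int:
        return self.Y_train.shape[1]

    def standardized(self) -> "Dataset":
        """Copy with each feature centered and scaled by the train-split
        mean and standard deviation (constant columns are left at zero).
        Full-batch ReLU training on raw positive-mean features tends to
        kill hidden units, so trainers operate on standardized data."""
        mu = self.X_train.mean(axis=0)
        sd = self.X_train.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return Dataset(
            X_train=(self.X_train - mu) / sd,
            Y_train=self.Y_train,
            X_test=(self.X_test - mu) / sd,
            Y_test=self.Y_test,
            important_idx=self.important_idx,
            names=self.names,
        )

    @property
    def labels_train(self) -> np.ndarray:
        return np.argmax(self.Y_train, axis=1)

    @property
    def labels_test(self) -> np.ndarray:
        return np.argmax(self.Y_test, axis=1)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: layer sizes H_0..H_L with H_0 = n features and
    H_L = n classes; hidden activation ReLU, output softmax."""

    layer_sizes: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_sizes", tuple(int(h) for h in self.layer_sizes))
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if any(h < 1 for h in self.layer_sizes):
            raise ValueError("layer sizes must be >= 1")

    @property
    def n_layers(self) -> int:
        """Number of weight layers L."""
        return len(self.layer_sizes) - 1


class NetworkParams:
    """All weights and biases of an MLP.

    ``weights[l]`` has shape (H_l, H_{l+1}) — row i is the outgoing
    connection group of neuron i of layer l. ``biases[l]`` has length
    H_{l+1}. ``flatten``/``set_flat`` expose the canonical flat view.
    """

    def __init__(self, spec: NetworkSpec, weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]):
        self.spec = spec
        self.weights = [np.asarray(w, dtype=np.float64) for w in weights]
        self.biases = [np.asarray(b, dtype=np.float64) for b in biases]
        sizes = spec.layer_sizes
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l], sizes[l + 1]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l}: inconsistent shapes {w.shape}, {b.shape}")

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    @property
    def n_weights(self) -> int:
        """Connection weights only, biases excluded."""
        return sum(w.size for w in self.weights)

    def flatten(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b)
        return np.concatenate(parts)

    def set_flat(self, v: np.ndarray) -> None:
        v = np.asarray(v, dtype=np.float64)
        if v.size != self.n_params:
            raise ValueError("flat vector length mismatch")
        off = 0
        for w, b in zip(self.weights, self.biases):
            w[...] = v[off : off + w.size].reshape(w.shape)
            off += w.size
            b[...] = v[off : off + b.size]
            off += b.size

    def add_flat(self, v: np.ndarray) -> None:
        """In-place θ ← θ + v for a flat vector v (the gradient step)."""
        v = np.asarray(v, dtype=np.float64)
        off = 0
        for w, b in zip(self.weights, self.biases):
            w += v[off : off + w.size].reshape(w.shape)
            off += w.size
            b += v[off : off + b.size]
            off += b.size

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.spec, [w.copy() for w in self.weights], [b.copy() for b in self.biases]
        )


@dataclass
class GroupStructure:
    """Connection groups: one per input neuron, one per hidden neuron.

    Groups are numpy row views onto the owning NetworkParams — mutating
    the parameters mutates the groups.
    """

    input_groups: list[np.ndarray] = field(default_factory=list)
    hidden_groups: list[np.ndarray] = field(default_factory=list)
    input_owners: list[tuple[int, int]] = field(default_factory=list)
    hidden_owners: list[tuple[int, int]] = field(default_factory=list)

    @property
    def all_groups(self) -> list[np.ndarray]:
        return self.input_groups + self.hidden_groups


def init_network(spec: NetworkSpec) -> NetworkParams:
    """Reproducible random initialization: weights uniform in
    ±1/sqrt(fan_in), biases zero."""
    rng = np.random.default_rng(spec.seed)
    weights, biases = [], []
    for l in range(spec.n_layers):
        fan_in = spec.layer_sizes[l]
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, spec.layer_sizes[l + 1])))
        biases.append(np.zeros(spec.layer_sizes[l + 1]))
    return NetworkParams(spec, weights, biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(params: NetworkParams, X: np.ndarray, return_hidden: bool = False):
    """Posterior class probabilities for each row of X.

    With ``return_hidden=True`` also returns the per-layer activations
    (input included) as needed for backpropagation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != params.spec.layer_sizes[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.spec.layer_sizes[0]}"
        )
    activations = [X]
    a = X
    L = params.spec.n_layers
    for l in range(L - 1):
        a = np.maximum(a @ params.weights[l] + params.biases[l], 0.0)
        activations.append(a)
    probs = _softmax(a @ params.weights[L - 1] + params.biases[L - 1])
    if return_hidden:
        return probs, activations
    return probs


def predict(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Class labels: argmax of the posterior, ties to the lowest index."""
    return np.argmax(forward(params, X), axis=1)


def extract_groups(params: NetworkParams) -> GroupStructure:
    """Connection-group view: input groups are rows of the first weight
    matrix, hidden groups are rows of the remaining ones. Every weight
    belongs to exactly one group."""
    gs = GroupStructure()
    for i in range(params.weights[0].shape[0]):
        gs.input_groups.append(params.weights[0][i])
        gs.input_owners.append((0, i))
    for l in range(1, params.spec.n_layers):
        for i in range(params.weights[l].shape[0]):
            gs.hidden_groups.append(params.weights[l][i])
            gs.hidden_owners.append((l, i))
    return gs


def save_params(params: NetworkParams, path: str) -> None:
    """Serialize to JSON: spec + base64 little-endian float64 payload in
    the canonical flat order."""
    flat = params.flatten().astype("<f8")
    doc = {
        "format": "bfselect-mlp",
        "version": _SERIAL_VERSION,
        "layer_sizes": list(params.spec.layer_sizes),
        "seed": params.spec.seed,
        "dtype": "<f8",
        "data": base64.b64encode(flat.tobytes()).decode("ascii"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_params(path: str) -> NetworkParams:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "bfselect-mlp":
        raise ValueError("not a bfselect model file")
    spec = NetworkSpec(tuple(doc["layer_sizes"]), seed=doc.get("seed", 0))
    flat = np.frombuffer(base64.b64decode(doc["data"]), dtype=doc["dtype"]).astype(np.float64)
    params = init_network(spec)
    params.set_flat(flat)
    return params
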