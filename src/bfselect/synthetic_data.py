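"""Synthetic HDLSS classification data.

Emulates the benchmark construction: a block of informative features in
which each class is a standard-normal cloud around its own centroid, and
a block of label-independent uniform noise features. Columns are
shuffled and the informative positions recorded, so feature-selection
quality can be scored exactly. Both presets keep the number of training
samples below the feature count (the high-dimension low-sample-size
regime).

Presets:

* ``ad1`` — 900 train / 2100 test, 2000 features (50 informative),
  2 classes; the easier binary problem.
* ``ad2`` — 900 train / 2100 test, 3000 features (100 informative),
  3 classes; harder: more classes and a lower informative-to-noise
  ratio.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from bfselect.mlp_core import Dataset

__all__ = ["SynthSpec", "generate", "ad1", "ad2", "write_dataset", "read_dataset"]


@dataclass(frozen=True)
class SynthSpec:
    n_train: int
    n_test: int
    p: int
    p_informative: int
    K_classes: int = 2
    class_sep: float = 1.0
    noise_low: float = 0.0
    noise_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_informative > self.p or self.p_informative < 1:
            raise ValueError("need 1 <= p_informative <= p")
        if self.n_train + self.n_test < self.K_classes:
            raise ValueError("too few samples for the number of classes")
        if self.K_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.p_informative < self.K_classes:
            raise ValueError("p_informative must be >= K_classes for separated centroids")
        if self.class_sep <= 0 or self.noise_high <= self.noise_low:
            raise ValueError("invalid separation or noise bounds")


def _centroids(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    """K orthonormal directions in the informative subspace, scaled so
    every pair of centroids sits exactly class_sep apart."""
    raw = rng.standard_normal((spec.K_classes, spec.p_informative))
    q, _ = np.linalg.qr(raw.T)
    return q.T[: spec.K_classes] * (spec.class_sep / np.sqrt(2.0))


def generate(spec: SynthSpec) -> Dataset:
    """Generate a balanced, column-shuffled HDLSS dataset."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_train + spec.n_test
    K = spec.K_classes
    # balanced labels over the whole pool
    counts = np.full(K, n_total // K)
    counts[: n_total % K] += 1
    labels = np.repeat(np.arange(K), counts)
    centroids = _centroids(rng, spec)
    informative = centroids[labels] + rng.standard_normal((n_total, spec.p_informative))
    noise = rng.uniform(spec.noise_low, spec.noise_high, size=(n_total, spec.p - spec.p_informative))
    X = np.concatenate([informative, noise], axis=1)
    col_perm = rng.permutation(spec.p)
    X = X[:, np.argsort(col_perm)]  # column col_perm[j] holds original column j
    important_idx = np.sort(col_perm[: spec.p_informative])
    # stratified shuffle then per-class proportional split
    order = rng.permutation(n_total)
    X, labels = X[order], labels[order]
    train_counts = np.full(K, spec.n_train // K)
    train_counts[: spec.n_train % K] += 1
    train_mask = np.zeros(n_total, dtype=bool)
    for c in range(K):
        cls_rows = np.flatnonzero(labels == c)
        train_mask[cls_rows[: train_counts[c]]] = True
    Y = np.eye(K)[labels]
    return Dataset(
        X_train=X[train_mask],
        Y_train=Y[train_mask],
        X_test=X[~train_mask],
        Y_test=Y[~train_mask],
        important_idx=important_idx,
    )


def ad1(seed: int = 0) -> Dataset:
    """Binary preset: 900/2100 split, 2000 features, 50 informative."""
    return generate(ad1_spec(seed))


def ad2(seed: int = 0) -> Dataset:
    """Three-class preset: 900/2100 split, 3000 features, 100 informative."""
    return generate(ad2_spec(seed))


def ad1_spec(seed: int = 0) -> SynthSpec:
    # class_sep is the centroid distance; 3.8 puts the Bayes-optimal
    # accuracy near 0.97, so models are limited by how well they ignore
    # the 1950 noise columns rather than by class overlap
    return SynthSpec(n_train=900, n_test=2100, p=2000, p_informative=50,
                     K_classes=2, class_sep=3.8, seed=seed)


def ad2_spec(seed: int = 0) -> SynthSpec:
    # harder: three classes, lower informative-to-noise ratio, and a
    # smaller separation (Bayes ceiling near 0.85)
    return SynthSpec(n_train=900, n_test=2100, p=3000, p_informative=100,
                     K_classes=3, class_sep=2.9, seed=seed)


def write_dataset(data: Dataset, csv_path: str, sidecar_path: str | None = None,
                  spec: SynthSpec | None = None) -> None:
    """CSV with a trailing integer ``label`` column (train rows first),
    plus a JSON sidecar holding the split sizes, informative indices and
    generator spec."""
    X = np.vstack([data.X_train, data.X_test])
    y = np.concatenate([data.labels_train, data.labels_test])
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df["label"] = y
    df.to_csv(csv_path, index=False)
    if sidecar_path:
        doc = {
            "n_train": int(data.X_train.shape[0]),
            "n_test": int(data.X_test.shape[0]),
            "important_idx": [int(i) for i in (data.important_idx if data.important_idx is not None else [])],
        }
        if spec is not None:
            doc["spec"] = asdict(spec)
        with open(sidecar_path, "w") as fh:
            json.dump(doc, fh)


def read_dataset(csv_path: str, sidecar_path: str | None = None,
                 n_train: int | None = None) -> Dataset:
    """Load a CSV written by :func:`write_dataset` (or any dense CSV with
    a trailing ``label`` column). The train/test split comes from the
    sidecar, or from ``n_train``."""
    df = pd.read_csv(csv_path)
    if "label" not in df.columns:
        raise ValueError("CSV must contain a 'label' column")
    if df.isna().any().any():
        raise ValueError("missing values are not supported")
    y = df.pop("label").to_numpy(dtype=int)
    X = df.to_numpy(dtype=float)
    important = None
    if sidecar_path:
        with open(sidecar_path) as fh:
            doc = json.load(fh)
        n_train = doc["n_train"]
        important = doc.get("important_idx") or None
    if n_train is None:
        raise ValueError("need a sidecar or n_train to split the data")
    K = int(y.max()) + 1
    Y = np.eye(K)[y]
    return Dataset(
        X_train=X[:n_train], Y_train=Y[:n_train],
        X_test=X[n_train:], Y_test=Y[n_train:],
        important_idx=important, names=list(df.columns),
    )
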