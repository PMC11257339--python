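import numpy as np
import pytest

from bfselect.mlp_core import Dataset, NetworkSpec, init_network
from bfselect.synthetic_data import SynthSpec, generate


@pytest.fixture
def tiny_net():
    """A (4, 3, 2) network with fixed seed."""
    return init_network(NetworkSpec((4, 3, 2), seed=7))


@pytest.fixture
def small_data():
    """A small, well-separated HDLSS-ish dataset (p=60, 10 informative)."""
    return generate(SynthSpec(n_train=60, n_test=120, p=60, p_informative=10,
                              K_classes=2, class_sep=4.0, seed=3))


@pytest.fixture
def toy_dataset():
    """A 2-feature, linearly separable two-class problem where both
    objectives are O(1): exercises trainers on a benign scale."""
    rng = np.random.default_rng(0)
    n = 40
    X0 = rng.normal(loc=(-1.5, 0.0), scale=0.4, size=(n, 2))
    X1 = rng.normal(loc=(+1.5, 0.0), scale=0.4, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    Y = np.eye(2)[y]
    idx = rng.permutation(2 * n)
    X, Y = X[idx], Y[idx]
    return Dataset(X_train=X[:50], Y_train=Y[:50], X_test=X[50:], Y_test=Y[50:],
                   important_idx=[0])
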