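import numpy as np
import pytest

from enhancernet.network import RegulatoryNetwork


def make_random_symmetric_net(rng, n_enhancers=4, n_tfs=6, beta=5.0,
                              unit_norm=False, with_weights=False):
    """Random nonnegative Xi with Q = Xi (reciprocal network)."""
    xi = rng.uniform(0.0, 1.0, size=(n_enhancers, n_tfs))
    if unit_norm:
        xi /= np.linalg.norm(xi, axis=1, keepdims=True)
    w = rng.normal(0.0, 0.3, n_enhancers) if with_weights \
        else np.zeros(n_enhancers)
    return RegulatoryNetwork(
        tf_names=tuple(f"TF{j}" for j in range(n_tfs)),
        enhancer_names=tuple(f"EN{i}" for i in range(n_enhancers)),
        binding=xi, coupling=xi.copy(), weights=w, beta=beta)


def make_unit_pair_net(cosine, beta=5.0, n_tfs=5):
    """Two unit-norm nonnegative patterns with a prescribed cosine."""
    a = np.zeros(n_tfs)
    b = np.zeros(n_tfs)
    a[0] = 1.0
    b[0] = cosine
    b[1] = np.sqrt(1.0 - cosine ** 2)
    xi = np.vstack([a, b])
    return RegulatoryNetwork(
        tf_names=tuple(f"TF{j}" for j in range(n_tfs)),
        enhancer_names=("A", "B"),
        binding=xi, coupling=xi.copy(), weights=np.zeros(2), beta=beta)


def make_sparse_pattern_net(rng, n_patterns=5, n_tfs=12, n_active=3,
                            beta=50.0):
    """Distinct sparse unit-norm patterns (reprogramming test bed)."""
    seen = set()
    rows = []
    while len(rows) < n_patterns:
        pos = tuple(sorted(rng.choice(n_tfs, size=n_active, replace=False)))
        if pos in seen:
            continue
        seen.add(pos)
        row = np.zeros(n_tfs)
        row[list(pos)] = rng.uniform(0.5, 1.5, n_active)
        rows.append(row / np.linalg.norm(row))
    xi = np.array(rows)
    return RegulatoryNetwork(
        tf_names=tuple(f"TF{j}" for j in range(n_tfs)),
        enhancer_names=tuple(f"P{i}" for i in range(n_patterns)),
        binding=xi, coupling=xi.copy(), weights=np.zeros(n_patterns),
        beta=beta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_symmetric_net(rng):
    return make_random_symmetric_net(rng)
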