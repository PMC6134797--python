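import numpy as np
import pandas as pd
import pytest

from priolasso import BlockSpec, Dataset, Outcome


def make_dataset(X, blocks, outcome, priority=None, sample_ids=None):
    """Assemble a Dataset from an ndarray and a {block: features} mapping."""
    feats = [f for fs in blocks.values() for f in fs]
    Xdf = pd.DataFrame(np.asarray(X, float), columns=feats, index=sample_ids)
    return Dataset(Xdf, BlockSpec(blocks, priority=priority), outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_block_continuous():
    """n=80, blocks A (3 features, signal) and B (2 features, noise)."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(80, 5))
    y = 1.5 * X[:, 0] - X[:, 1] + 0.5 * rng.normal(size=80)
    return make_dataset(
        X,
        {"A": ["a1", "a2", "a3"], "B": ["b1", "b2"]},
        Outcome.continuous(y),
    )


def simple_survival(n=60, seed=0, beta=None, p=4, cens_scale=2.0):
    """Exponential survival with censoring; returns (X, time, status)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = X @ (np.zeros(p) if beta is None else np.asarray(beta, float))
    T = rng.exponential(scale=np.exp(-eta))
    C = rng.exponential(scale=cens_scale, size=n)
    time = np.minimum(T, C) + 1e-9
    status = (T <= C).astype(int)
    return X, time, status
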