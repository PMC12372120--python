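import numpy as np
import pytest

from macnet.data import LabeledTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(n_per_class, n_features=4, seed=0, spread=1.0, separation=4.0):
    """Small labeled table with well-separated Gaussian classes."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for c, n_c in enumerate(n_per_class):
        center = np.zeros(n_features)
        center[c % n_features] = separation * (c + 1)
        feats.append(center + rng.standard_normal((n_c, n_features)) * spread)
        labels.append(np.full(n_c, c, dtype=np.int64))
    X = np.vstack(feats)
    y = np.concatenate(labels)
    perm = rng.permutation(len(y))
    return LabeledTable(
        features=X[perm],
        labels=y[perm],
        row_ids=np.arange(len(y)),
        feature_names=[f"f{j}" for j in range(n_features)],
        n_classes=len(n_per_class),
    )


@pytest.fixture
def small_table():
    return make_table([60, 25, 15], seed=7)
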