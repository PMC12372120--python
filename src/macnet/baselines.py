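"""Comparison methods: focal loss, SMOTE, random undersampling, Δ-gap.

These are the standard imbalance-handling baselines the two-stage framework
is measured against. SMOTE and undersampling rebalance the data itself;
focal loss reweights the objective with a *static* rule, in contrast to the
error-driven dynamic weights of MAAL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data import LabeledTable
from .losses import PROB_FLOOR, _check_probs

__all__ = [
    "FocalParams",
    "focal_loss",
    "smote",
    "random_undersample",
    "delta_gap",
]


@dataclass(frozen=True)
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def focal_loss(probs, labels, params: FocalParams = FocalParams()) -> float:
    """Batch mean of ``-alpha * (1 - p_t)^gamma * log(p_t)``.

    ``p_t`` is the predicted probability of the true class. With gamma=0 and
    alpha=1 this reduces to plain cross-entropy.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_probs(probs, labels)
    p_t = np.maximum(probs[np.arange(len(labels)), labels], PROB_FLOOR)
    return float(np.mean(-params.alpha * (1 - p_t) ** params.gamma * np.log(p_t)))


def smote(table: LabeledTable, k: int = 5, seed: int = 0) -> LabeledTable:
    """Synthetic minority oversampling until all class counts are equalized.

    Each synthetic point is ``x_i + lambda * (x_j - x_i)`` with ``x_j`` drawn
    uniformly from the k nearest same-class neighbors of a random class
    member ``x_i`` (Euclidean metric, neighbor ties broken by lower row id)
    and ``lambda ~ U[0, 1]``. Synthetic rows receive fresh negative row ids
    so they are recognizably not original samples.
    """
    rng = np.random.default_rng(seed)
    counts = table.class_counts()
    target = counts.max()
    feats = [table.features]
    labels = [table.labels]
    next_id = -1
    new_ids: list[int] = []
    for c in range(table.n_classes):
        n_c = int(counts[c])
        deficit = int(target - n_c)
        if deficit == 0:
            continue
        if n_c == 1:
            raise ValueError(f"class {c} has a single member; SMOTE undefined")
        members = np.flatnonzero(table.labels == c)
        # stable neighbor geometry: order class members by row id
        members = members[np.argsort(table.row_ids[members], kind="stable")]
        X = table.features[members]
        k_eff = min(k, n_c - 1)
        if k_eff < k:
            warnings.warn(
                f"class {c} has only {n_c} members; lowering k to {k_eff}")
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
        _, neigh = nn.kneighbors(X)  # column 0 is the point itself
        synth = np.empty((deficit, table.n_features))
        for m in range(deficit):
            i = rng.integers(n_c)
            j = neigh[i, 1 + rng.integers(k_eff)]
            lam = rng.random()
            synth[m] = X[i] + lam * (X[j] - X[i])
        feats.append(synth)
        labels.append(np.full(deficit, c, dtype=np.int64))
        new_ids.extend(range(next_id, next_id - deficit, -1))
        next_id -= deficit
    return replace(
        table,
        features=np.vstack(feats),
        labels=np.concatenate(labels),
        row_ids=np.concatenate([table.row_ids, np.array(new_ids, dtype=np.int64)])
        if new_ids else table.row_ids,
    )


def random_undersample(table: LabeledTable, seed: int = 0) -> LabeledTable:
    """Downsample every class, without replacement, to the minority count."""
    counts = table.class_counts()
    if (counts > 0).sum() < 2:
        raise ValueError("undersampling needs at least two classes")
    target = counts[counts > 0].min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in range(table.n_classes):
        members = np.flatnonzero(table.labels == c)
        if len(members) > target:
            members = rng.choice(members, size=target, replace=False)
        keep.append(np.sort(members))
    return table.subset_rows(np.concatenate(keep))


def delta_gap(train_losses, val_losses) -> float:
    """Final-epoch training loss minus final-epoch validation loss.

    A large negative value (validation well above training) is the
    overfitting signature this diagnostic exists to expose.
    """
    train_losses = np.asarray(train_losses, dtype=np.float64)
    val_losses = np.asarray(val_losses, dtype=np.float64)
    if train_losses.size == 0 or train_losses.size != val_losses.size:
        raise ValueError("loss series must be non-empty and equal length")
    return float(train_losses[-1] - val_losses[-1])
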