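"""Labeled tabular data: loading, feature selection, splitting, standardization.

Every table carries persistent original row identifiers (``row_ids``) from the
moment a file is read. Those identifiers survive feature selection, splitting
and scaling unchanged, which is what makes the downstream train/test leakage
isolation of the error bank provable rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

__all__ = [
    "LabeledTable",
    "ScalerParams",
    "SplitResult",
    "load_csv",
    "mrmr_select",
    "stratified_split",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
]


@dataclass
class LabeledTable:
    """A numeric feature matrix with integer class labels and stable row ids.

    Parameters
    ----------
    features : (n_samples, n_features) float array
    labels : (n_samples,) int array with values in ``{0..n_classes-1}``
    row_ids : (n_samples,) int array of original file row positions; unique
    feature_names : list of str, one per feature column
    n_classes : total number of classes ``C`` (may exceed the classes present
        in a split of the table, never be smaller than ``labels.max()+1``)
    """

    features: np.ndarray
    labels: np.ndarray
    row_ids: np.ndarray
    feature_names: list[str]
    n_classes: int
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.row_ids = np.asarray(self.row_ids, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.row_ids) != n:
            raise ValueError(
                f"length mismatch: {n} feature rows, {len(self.labels)} labels, "
                f"{len(self.row_ids)} row_ids"
            )
        if len(set(self.row_ids.tolist())) != n:
            raise ValueError("row_ids must be unique")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names must match feature columns")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels must lie in {0..n_classes-1}")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset_rows(self, idx: np.ndarray) -> "LabeledTable":
        """Row subset by positional index; row_ids propagate unchanged."""
        idx = np.asarray(idx)
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            row_ids=self.row_ids[idx],
        )

    def subset_columns(self, names: list[str]) -> "LabeledTable":
        cols = [self.feature_names.index(m) for m in names]
        return replace(
            self, features=self.features[:, cols], feature_names=list(names)
        )


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean and (population, ddof=0) standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_names: tuple = ()


@dataclass(frozen=True)
class SplitResult:
    train: LabeledTable
    test: LabeledTable
    train_fraction: float
    seed: int


def load_csv(path, label_column: str) -> LabeledTable:
    """Read an RFC-4180 CSV with a header row into a :class:`LabeledTable`.

    Labels are re-encoded to contiguous codes ``0..C-1`` in sorted order of
    the original values; the mapping is kept on ``label_mapping``. Any missing
    or non-numeric feature cell aborts the load, naming its coordinates.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        numeric = pd.to_numeric(feats[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"missing or non-numeric value at row {row}, column {col!r}"
            )
        feats[col] = numeric
    raw_labels = df[label_column]
    if raw_labels.isna().any():
        row = int(np.flatnonzero(raw_labels.isna().to_numpy())[0])
        raise ValueError(f"missing label at row {row}, column {label_column!r}")
    classes = sorted(pd.unique(raw_labels).tolist())
    if len(classes) < 2:
        raise ValueError("file contains a single class; classification undefined")
    mapping = {orig: code for code, orig in enumerate(classes)}
    labels = raw_labels.map(mapping).to_numpy(dtype=np.int64)
    return LabeledTable(
        features=feats.to_numpy(dtype=np.float64),
        labels=labels,
        row_ids=np.arange(len(df)),
        feature_names=list(feats.columns),
        n_classes=len(classes),
        label_mapping=mapping,
    )


def _discretize(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to one bin."""
    codes = pd.qcut(column, q=n_bins, labels=False, duplicates="drop")
    codes = np.asarray(codes)
    if np.isnan(codes).any():  # constant column: qcut yields all-NaN codes
        return np.zeros(len(column), dtype=np.int64)
    return codes.astype(np.int64)


def mrmr_select(
    table: LabeledTable, k: int, n_bins: int = 10
) -> tuple[LabeledTable, list[str]]:
    """Greedy minimum-redundancy maximum-relevance feature selection.

    Uses the difference (MID) criterion: the first feature maximizes mutual
    information with the label; each subsequent pick maximizes
    ``relevance - mean(redundancy with already-selected features)``, with both
    terms measured as mutual information between equal-frequency discretized
    columns. Ties break toward the lower feature index. A constant feature has
    zero mutual information with everything, so it can never beat an
    informative candidate.
    """
    p = table.n_features
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, {p}]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    disc = [_discretize(table.features[:, j], n_bins) for j in range(p)]
    relevance = np.array([mutual_info_score(d, table.labels) for d in disc])

    selected: list[int] = []
    remaining = list(range(p))
    red = np.zeros(p)  # running sum of MI with selected features
    while len(selected) < k:
        if selected:
            score = relevance - red / len(selected)
        else:
            score = relevance.copy()
        best = min(
            remaining, key=lambda j: (-score[j], j)
        )  # max score, ties -> lowest index
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            red[j] += mutual_info_score(disc[j], disc[best])
    names = [table.feature_names[j] for j in selected]
    return table.subset_columns(names), names


def _largest_remainder(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Allocate ``fraction`` of each class count, preserving the total exactly."""
    exact = counts * fraction
    base = np.floor(exact).astype(np.int64)
    total = int(round(counts.sum() * fraction))
    deficit = total - base.sum()
    remainders = exact - base
    order = sorted(range(len(counts)), key=lambda i: (-remainders[i], i))
    for i in order[: max(deficit, 0)]:
        base[i] += 1
    return base


def stratified_split(
    table: LabeledTable, train_fraction: float, seed: int
) -> SplitResult:
    """Seeded stratified split with largest-remainder per-class allocation.

    Per-class training counts are the largest-remainder rounding of
    ``train_fraction`` times each class total; membership within a class is a
    seeded shuffle. Identical inputs always yield the identical partition.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    counts = table.class_counts()
    for c, cnt in enumerate(counts):
        if cnt == 1:
            raise ValueError(f"class {c} has a single member; cannot stratify")
    train_counts = _largest_remainder(counts, train_fraction)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in range(table.n_classes):
        members = np.flatnonzero(table.labels == c)
        perm = rng.permutation(len(members))
        train_idx.append(members[perm[: train_counts[c]]])
        test_idx.append(members[perm[train_counts[c]:]])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return SplitResult(
        train=table.subset_rows(tr),
        test=table.subset_rows(te),
        train_fraction=train_fraction,
        seed=seed,
    )


def fit_scaler(train: LabeledTable) -> ScalerParams:
    """Fit per-feature standardization on the training partition only.

    sigma uses the population convention (divide by n). A zero-variance
    feature is an error: its z-score is undefined.
    """
    mu = train.features.mean(axis=0)
    sigma = train.features.std(axis=0, ddof=0)
    for j, s in enumerate(sigma):
        if s <= 0:
            raise ValueError(
                f"feature {train.feature_names[j]!r} has zero variance at fit time"
            )
    return ScalerParams(mu=mu, sigma=sigma, feature_names=tuple(train.feature_names))


def apply_scaler(table: LabeledTable, params: ScalerParams) -> LabeledTable:
    """z-score every feature: (x - mu) / sigma."""
    if table.n_features != len(params.mu):
        raise ValueError("scaler fitted on a different number of features")
    return replace(table, features=(table.features - params.mu) / params.sigma)


def invert_scaler(table: LabeledTable, params: ScalerParams) -> LabeledTable:
    """Undo :func:`apply_scaler` (x * sigma + mu)."""
    return replace(table, features=table.features * params.sigma + params.mu)
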