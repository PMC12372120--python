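"""Misclassified-sample bookkeeping with a hard train/test isolation guarantee.

During primary training, every best-checkpoint event records the row ids the
model currently misclassifies on the training split; after training, the
final model's test-set mistakes are recorded separately. The two id sets feed
the secondary correction network (train side) and its evaluation (test side),
so any overlap between them would leak test information into training. The
bank therefore keys everything on the original file row ids, deduplicates by
set semantics, and refuses to materialize data until an explicit leakage
check passes — both on ids and on exact (bitwise) feature-row content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledTable, SplitResult

logger = logging.getLogger(__name__)

__all__ = ["ErrorBank", "LeakageReport", "materialize"]


@dataclass
class LeakageReport:
    passed: bool
    overlapping_ids: list = field(default_factory=list)
    duplicate_content_pairs: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


class ErrorBank:
    """Accumulates misclassified row ids with per-checkpoint provenance."""

    def __init__(self, train_row_ids, test_row_ids):
        self._train_pool = frozenset(int(i) for i in np.asarray(train_row_ids))
        self._test_pool = frozenset(int(i) for i in np.asarray(test_row_ids))
        if self._train_pool & self._test_pool:
            raise ValueError("train and test splits share row ids")
        self.train_error_ids: set[int] = set()
        self.test_error_ids: set[int] = set()
        # row_id -> list of (checkpoint_id, predicted, true)
        self.provenance: dict[int, list] = {}

    def _record(self, pool, target: set, checkpoint_id, row_ids, predicted,
                true_labels, side: str) -> None:
        row_ids = np.asarray(row_ids)
        predicted = np.asarray(predicted)
        true_labels = np.asarray(true_labels)
        if not (len(row_ids) == len(predicted) == len(true_labels)):
            raise ValueError("row_ids, predicted and true_labels must align")
        outside = [int(i) for i in row_ids if int(i) not in pool]
        if outside:
            raise ValueError(
                f"row ids {outside[:5]} do not belong to the {side} split"
            )
        for rid, p, t in zip(row_ids, predicted, true_labels):
            if p != t:
                rid = int(rid)
                target.add(rid)
                self.provenance.setdefault(rid, []).append(
                    (checkpoint_id, int(p), int(t))
                )

    def record_epoch_errors(self, checkpoint_id, row_ids, predicted,
                            true_labels) -> "ErrorBank":
        """Union the training-split mistakes of one saved best checkpoint."""
        self._record(self._train_pool, self.train_error_ids, checkpoint_id,
                     row_ids, predicted, true_labels, "training")
        return self

    def record_test_errors(self, row_ids, predicted, true_labels) -> "ErrorBank":
        """Record the final model's test-split mistakes."""
        self._record(self._test_pool, self.test_error_ids, "final",
                     row_ids, predicted, true_labels, "test")
        return self

    def check_leakage(self, train_table: LabeledTable | None = None,
                      test_table: LabeledTable | None = None) -> LeakageReport:
        """Pass iff the banked id sets are disjoint and, when tables are
        given, no identical feature row appears on both sides (bitwise
        equality of the standardized rows)."""
        overlap = sorted(self.train_error_ids & self.test_error_ids)
        dup_pairs = []
        if train_table is not None and test_table is not None:
            tr_rows = {
                train_table.features[i].tobytes(): int(train_table.row_ids[i])
                for i in range(train_table.n_samples)
                if int(train_table.row_ids[i]) in self.train_error_ids
            }
            for i in range(test_table.n_samples):
                rid = int(test_table.row_ids[i])
                if rid not in self.test_error_ids:
                    continue
                key = test_table.features[i].tobytes()
                if key in tr_rows:
                    dup_pairs.append((tr_rows[key], rid))
        report = LeakageReport(
            passed=not overlap and not dup_pairs,
            overlapping_ids=overlap,
            duplicate_content_pairs=dup_pairs,
        )
        if not report.passed:
            logger.warning(
                "leakage violation: %d overlapping ids, %d duplicated rows",
                len(overlap), len(dup_pairs))
        return report

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "train_error_ids": sorted(self.train_error_ids),
                "test_error_ids": sorted(self.test_error_ids),
                "provenance": {
                    str(k): v for k, v in sorted(self.provenance.items())
                },
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def materialize(
    bank: ErrorBank,
    split: SplitResult,
    primary_net=None,
    mode: str = "embeddings",
) -> tuple[dict, dict]:
    """Assemble the secondary model's train/test data from the banked ids.

    Returns two dicts with keys ``inputs`` (embeddings or raw features),
    ``labels`` and ``row_ids``. Refuses to run if the leakage check fails.
    Logs both sides' per-class counts (the shape of the error-distribution
    table in the study protocol).
    """
    report = bank.check_leakage(split.train, split.test)
    if not report:
        raise ValueError(f"leakage violation, refusing to materialize: {report}")
    if not bank.train_error_ids:
        raise ValueError("secondary model has no training data (empty error bank)")

    def gather(table: LabeledTable, ids: set[int]) -> dict:
        pos = [i for i in range(table.n_samples)
               if int(table.row_ids[i]) in ids]
        feats = table.features[pos]
        if mode == "embeddings":
            if primary_net is None:
                raise ValueError("embeddings mode requires the primary network")
            inputs = primary_net.embed(feats) if len(pos) else np.empty((0, 64))
        elif mode == "raw_features":
            inputs = feats
        else:
            raise ValueError(f"unknown materialization mode {mode!r}")
        return {
            "inputs": inputs,
            "labels": table.labels[pos],
            "row_ids": table.row_ids[pos],
            "n_classes": table.n_classes,
        }

    train_side = gather(split.train, bank.train_error_ids)
    test_side = gather(split.test, bank.test_error_ids)
    for name, side in (("train", train_side), ("test", test_side)):
        counts = np.bincount(side["labels"], minlength=split.train.n_classes)
        logger.info("%s-side error samples per class: %s", name, counts.tolist())
    return train_side, test_side
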