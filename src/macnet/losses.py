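"""Misclassification-aware adaptive loss (MAAL).

MAAL is a weighted cross-entropy whose per-class weights are driven by where
the model currently errs. After each training epoch the misclassified-sample
counts per true class are converted to error *shares*

    rate_i = errors_i / sum_j errors_j,

exponentially amplified, w_i = exp(rate_i), and clipped to a configured range.
Updates are withheld for a warm-up of ``update_delay`` epochs so the network
first stabilizes under uniform weights. Because shares lie in [0, 1], the
literal rule keeps every weight inside [1, e]; the wider clip range is a
safeguard that only binds under the alternative per-class rate mode
(``errors_i / class size`` can still not exceed e, but custom rate modes
might).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassWeightState",
    "class_error_rates",
    "update_weights",
    "maal",
    "cross_entropy",
    "PROB_FLOOR",
]

PROB_FLOOR = 1e-12  # probability floor applied before log


@dataclass
class ClassWeightState:
    """Per-class MAAL weights plus schedule state and update history."""

    n_classes: int
    update_delay: int = 60
    clip_lo: float = 1.0
    clip_hi: float = 5.0
    rate_mode: str = "share_of_errors"  # or "per_class"
    weights: np.ndarray = None
    history: list = field(default_factory=list)  # (epoch, weight vector) pairs

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(self.n_classes)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.rate_mode not in ("share_of_errors", "per_class"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")

    def history_array(self) -> np.ndarray:
        """History as an (n_updates, 1 + C) array: epoch then weights."""
        if not self.history:
            return np.empty((0, 1 + self.n_classes))
        return np.array([[e, *w] for e, w in self.history])


def class_error_rates(errors) -> np.ndarray:
    """Share of the epoch's misclassifications attributable to each class.

    Returns the all-zero vector when no errors occurred (0/0 is defined as 0
    so a perfect epoch never perturbs the weights).
    """
    errors = np.asarray(errors, dtype=np.float64)
    if (errors < 0).any():
        raise ValueError("error counts must be non-negative")
    total = errors.sum()
    if total == 0:
        return np.zeros_like(errors)
    return errors / total


def update_weights(
    state: ClassWeightState,
    errors,
    epoch: int,
    class_sizes=None,
) -> ClassWeightState:
    """Apply one scheduled weight update in place; returns the state.

    No update happens before ``update_delay`` epochs (0-based: epochs
    ``0..delay-1`` are warm-up) or on a zero-error epoch; either leaves the
    weights, and the history, untouched.
    """
    errors = np.asarray(errors, dtype=np.float64)
    if len(errors) != state.n_classes:
        raise ValueError("error counts length must equal n_classes")
    if epoch < state.update_delay:
        return state
    if errors.sum() == 0:
        return state
    if state.rate_mode == "per_class":
        if class_sizes is None:
            raise ValueError("per_class rate mode requires class_sizes")
        sizes = np.asarray(class_sizes, dtype=np.float64)
        rates = np.where(sizes > 0, errors / np.maximum(sizes, 1), 0.0)
    else:
        rates = class_error_rates(errors)
    state.weights = np.clip(np.exp(rates), state.clip_lo, state.clip_hi)
    state.history.append((epoch, state.weights.copy()))
    return state


def _check_probs(probs: np.ndarray, labels: np.ndarray) -> None:
    if probs.ndim != 2:
        raise ValueError("probs must be (batch, n_classes)")
    if len(labels) != probs.shape[0]:
        raise ValueError("labels length must match batch size")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability row must sum to 1")


def maal(probs, labels, weights) -> float:
    """Weighted cross-entropy: batch mean of ``-w[y] * log p[y]``.

    With all weights equal to 1 this is exactly plain cross-entropy.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    _check_probs(probs, labels)
    if len(weights) != probs.shape[1]:
        raise ValueError("weights length must equal n_classes")
    p_true = np.maximum(probs[np.arange(len(labels)), labels], PROB_FLOOR)
    return float(np.mean(-weights[labels] * np.log(p_true)))


def cross_entropy(probs, labels) -> float:
    """Plain multiclass cross-entropy (MAAL at uniform weights)."""
    probs = np.asarray(probs, dtype=np.float64)
    return maal(probs, labels, np.ones(probs.shape[1]))
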