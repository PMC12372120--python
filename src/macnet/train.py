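"""Two-stage training and joint classification.

Stage one trains the primary attention-MLP with the misclassification-aware
adaptive loss (MAAL): mini-batch AdamW, per-epoch class-error counts driving
the weight schedule after its warm-up delay, early stopping on a stratified
validation carve-out, and an error bank recording the training-split
mistakes at every best-checkpoint event. Stage two trains the lighter
correction network, with the same loss machinery, exclusively on the banked
error samples (their 64-d primary embeddings by default). Joint
classification routes test samples between the two models:

* ``oracle`` routing re-predicts exactly the samples the primary model got
  wrong. It needs the true labels, so it is an *evaluation protocol* — it
  bounds what correction can add — never a deployable classifier.
* ``confidence`` routing re-predicts samples whose primary softmax
  confidence falls below a threshold; label-free and deployable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import LabeledTable, stratified_split
from .error_bank import ErrorBank, materialize
from .losses import ClassWeightState, update_weights
from .nets import NetworkSpec, PrimaryNet, SecondaryNet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "JointClassifier",
    "train_primary",
    "train_secondary",
    "joint_predict",
    "AdamW",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    primary_epochs: int = 600
    secondary_epochs: int = 1000
    patience: int = 50
    weight_decay: float = 1e-5
    seed: int = 42
    val_fraction: float = 0.15
    maal_delay: int = 60
    maal_clip: tuple = (1.0, 5.0)
    maal_rate_mode: str = "share_of_errors"
    use_maal: bool = True

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.primary_epochs,
               self.secondary_epochs, self.patience) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.patience >= max(self.primary_epochs, self.secondary_epochs):
            raise ValueError("patience must be smaller than the epoch budget")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


class AdamW:
    """Adam with decoupled weight decay (weight decay applied to the
    parameters directly, not through the gradient moments)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            p.data *= 1.0 - self.lr * self.weight_decay
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _loss_tensor(logits, labels, weights):
    """MAAL on the graph: mean of -w[y] * log p[y] from raw logits."""
    logp = logits.log_softmax(axis=-1)
    picked = logp.take_rows(labels)
    return -(picked * Tensor(weights[labels])).mean()


def _eval_ce(net, X, y) -> float:
    """Inference-mode class-balanced (macro) cross-entropy.

    The monitored validation loss averages each class's mean cross-entropy
    with equal class weight. On imbalanced data a plain sample-mean monitor
    is dominated by the majority class and systematically selects
    majority-biased checkpoints, which would discard exactly the minority
    improvements the adaptive loss exists to produce.
    """
    logits, _ = net.forward(X, training=False)
    logp = logits.log_softmax(axis=-1).data
    per_sample = -logp[np.arange(len(y)), y]
    classes = np.unique(y)
    return float(np.mean([per_sample[y == c].mean() for c in classes]))


def _snapshot(net) -> list[np.ndarray]:
    return [p.data.copy() for p in net.params()]


def _restore(net, snap) -> None:
    for p, s in zip(net.params(), snap):
        p.data = s.copy()


def _fit_loop(net, X, y, Xval, yval, config: TrainConfig, epochs: int,
              rng: np.random.Generator,
              on_best=None) -> tuple[ClassWeightState, dict]:
    """Shared mini-batch loop with MAAL schedule and early stopping.

    ``on_best(epoch, checkpoint_id)`` fires at every best-checkpoint event.
    Returns the weight state and a history dict; the network is left holding
    the best parameters.
    """
    C = net.spec.out_dim
    state = ClassWeightState(
        n_classes=C, update_delay=config.maal_delay,
        clip_lo=config.maal_clip[0], clip_hi=config.maal_clip[1],
        rate_mode=config.maal_rate_mode)
    opt = AdamW(net.params(), lr=config.lr,
                weight_decay=config.weight_decay)
    n = len(y)
    best_loss = np.inf
    best_snap = _snapshot(net)
    best_epoch = -1
    since_best = 0
    checkpoint_id = 0
    hist = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, _ = net.forward(X[idx], training=True, rng=rng)
            loss = _loss_tensor(logits, y[idx], state.weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.data.item())
        # end-of-epoch error counts on the fit portion drive the schedule
        if config.use_maal:
            pred = net.predict(X)
            errors = np.bincount(y[pred != y], minlength=C)
            update_weights(state, errors, epoch,
                           class_sizes=np.bincount(y, minlength=C))
        val_loss = _eval_ce(net, Xval, yval)
        hist["train_loss"].append(float(np.mean(epoch_losses)))
        hist["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_snap = _snapshot(net)
            best_epoch = epoch
            since_best = 0
            checkpoint_id += 1
            if on_best is not None:
                on_best(epoch, checkpoint_id)
        else:
            since_best += 1
            if since_best >= config.patience:
                hist["stopped_epoch"] = epoch + 1  # 1-based count of epochs run
                break
    hist["best_epoch"] = best_epoch + 1
    hist["best_val_loss"] = best_loss
    if hist["stopped_epoch"] is None:
        hist["stopped_epoch"] = min(epochs, len(hist["train_loss"]))
    _restore(net, best_snap)
    return state, hist


def train_primary(
    train: LabeledTable,
    config: TrainConfig = TrainConfig(),
    spec: NetworkSpec | None = None,
) -> tuple[PrimaryNet, ErrorBank, ClassWeightState, dict]:
    """Train the primary classifier; returns (net, bank, weight_state, history).

    The error bank is seeded with the training split's row ids only; the
    caller records test-side errors after final evaluation. A stratified
    ``val_fraction`` carve-out of the training split is monitored for early
    stopping so the test set never influences checkpoint selection.
    """
    if train.n_samples == 0:
        raise ValueError("empty training table")
    counts = train.class_counts()
    absent = np.flatnonzero(counts == 0)
    if absent.size:
        raise ValueError(f"classes {absent.tolist()} absent from training split")
    ss = np.random.SeedSequence(config.seed)
    s_split, s_init, s_loop = (int(c.generate_state(1)[0] % (2**31))
                               for c in ss.spawn(3))
    inner = stratified_split(train, 1.0 - config.val_fraction, seed=s_split)
    fit_t, val_t = inner.train, inner.test
    if spec is None:
        spec = NetworkSpec(in_dim=train.n_features, out_dim=train.n_classes)
    net = PrimaryNet(spec, seed=s_init)
    rng = np.random.default_rng(s_loop)

    bank = ErrorBank(train.row_ids, np.array([], dtype=np.int64))

    def on_best(epoch, checkpoint_id):
        # record this checkpoint's mistakes over the FULL training split
        pred = net.predict(train.features)
        bank.record_epoch_errors(checkpoint_id, train.row_ids, pred,
                                 train.labels)

    cfg = config if config.use_maal else _uniform(config)
    state, hist = _fit_loop(
        net, fit_t.features, fit_t.labels, val_t.features, val_t.labels,
        cfg, config.primary_epochs, rng, on_best=on_best)
    logger.info("primary training stopped at epoch %s (best %s, val CE %.4f)",
                hist["stopped_epoch"], hist["best_epoch"], hist["best_val_loss"])
    return net, bank, state, hist


def _uniform(config: TrainConfig) -> TrainConfig:
    """Disable weight updates (uniform cross-entropy) without touching the loop."""
    from dataclasses import replace

    return replace(config, use_maal=False)


def _rebind_bank(bank: ErrorBank, test_row_ids) -> ErrorBank:
    out = ErrorBank(sorted(bank._train_pool), test_row_ids)
    out.train_error_ids = set(bank.train_error_ids)
    out.provenance = {k: list(v) for k, v in bank.provenance.items()}
    return out


def collect_test_errors(bank: ErrorBank, net: PrimaryNet,
                        test: LabeledTable) -> ErrorBank:
    """Record the final primary model's test-split mistakes into the bank."""
    bank = _rebind_bank(bank, test.row_ids)
    pred = net.predict(test.features)
    bank.record_test_errors(test.row_ids, pred, test.labels)
    return bank


def train_secondary(
    secondary_train: dict,
    config: TrainConfig = TrainConfig(),
    spec: NetworkSpec | None = None,
) -> tuple[SecondaryNet, ClassWeightState, dict]:
    """Train the correction network on materialized error-bank data.

    ``secondary_train`` is the train-side dict from
    :func:`macnet.error_bank.materialize`. With fewer than 20 samples the
    early-stopping monitor falls back to the training loss itself.
    """
    X = np.asarray(secondary_train["inputs"], dtype=np.float64)
    y = np.asarray(secondary_train["labels"], dtype=np.int64)
    if len(y) == 0:
        raise ValueError("secondary model has no training data")
    C = int(secondary_train.get("n_classes", int(y.max()) + 1))
    if len(np.unique(y)) == 1:
        logger.warning(
            "secondary training set contains a single class (%d); MAAL "
            "degenerates to weighted cross-entropy on that class", y[0])
    ss = np.random.SeedSequence(config.seed + 1)
    s_split, s_init, s_loop = (int(c.generate_state(1)[0] % (2**31))
                               for c in ss.spawn(3))
    if spec is None:
        spec = SecondaryNet.default_spec(in_dim=X.shape[1], out_dim=C)
    net = SecondaryNet(spec, seed=s_init)
    rng = np.random.default_rng(s_loop)
    # stratified 15% carve-out when feasible, else monitor training loss
    can_split = len(y) >= 20 and (np.bincount(y, minlength=C)[
        np.bincount(y, minlength=C) > 0] >= 2).all()
    if can_split:
        tbl = LabeledTable(X, y, np.arange(len(y)),
                           [f"e{j}" for j in range(X.shape[1])], C)
        inner = stratified_split(tbl, 1.0 - config.val_fraction, seed=s_split)
        Xf, yf = inner.train.features, inner.train.labels
        Xv, yv = inner.test.features, inner.test.labels
    else:
        Xf, yf, Xv, yv = X, y, X, y
    cfg = config if config.use_maal else _uniform(config)
    state, hist = _fit_loop(net, Xf, yf, Xv, yv, cfg,
                            config.secondary_epochs, rng)
    logger.info("secondary training stopped at epoch %s (best %s)",
                hist["stopped_epoch"], hist["best_epoch"])
    return net, state, hist


@dataclass
class JointClassifier:
    primary: PrimaryNet
    secondary: SecondaryNet
    routing: str = "oracle"  # or "confidence"
    confidence_threshold: float = 0.5
    secondary_mode: str = "embeddings"

    def __post_init__(self):
        if self.routing not in ("oracle", "confidence"):
            raise ValueError(f"unknown routing {self.routing!r}")
        if self.routing == "confidence" and not 0 < self.confidence_threshold < 1:
            raise ValueError("confidence threshold must lie in (0, 1)")


def joint_predict(jc: JointClassifier, test: LabeledTable,
                  true_labels=None) -> tuple[np.ndarray, dict]:
    """Combine primary and secondary predictions under the routing rule.

    Returns the final label vector and an audit dict listing the routed row
    ids with both models' predictions. Oracle routing requires true labels
    and reproduces the evaluation protocol only; it cannot ship.
    """
    probs = jc.primary.predict_proba(test.features)
    primary_pred = probs.argmax(axis=1)
    if jc.routing == "oracle":
        if true_labels is None:
            raise ValueError(
                "oracle routing needs true labels; it reproduces the "
                "evaluation protocol only — use confidence routing to deploy")
        routed = np.flatnonzero(primary_pred != np.asarray(true_labels))
    else:
        routed = np.flatnonzero(probs.max(axis=1) < jc.confidence_threshold)
    final = primary_pred.copy()
    audit = {"routing": jc.routing, "routed": []}
    if routed.size:
        if jc.secondary_mode == "embeddings":
            inputs = jc.primary.embed(test.features[routed])
        else:
            inputs = test.features[routed]
        sec_pred = jc.secondary.predict(inputs)
        final[routed] = sec_pred
        for pos, sp in zip(routed, sec_pred):
            audit["routed"].append({
                "row_id": int(test.row_ids[pos]),
                "primary": int(primary_pred[pos]),
                "secondary": int(sp),
            })
    return final, audit
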