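"""Two-stage training loop and joint-classification contracts."""

import numpy as np
import pytest

from macnet.data import (SplitResult, apply_scaler, fit_scaler,
                         stratified_split)
from macnet.error_bank import materialize
from macnet.nets import NetworkSpec, SecondaryNet
from macnet.train import (JointClassifier, TrainConfig, collect_test_errors,
                          joint_predict, train_primary, train_secondary)

from conftest import make_table


def quick_config(seed=0, **kw):
    defaults = dict(primary_epochs=12, secondary_epochs=15, patience=6,
                    maal_delay=4, seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def trained():
    """One small trained pipeline shared by the read-only tests below."""
    table = make_table([80, 30, 16], seed=21, spread=1.5)
    split = stratified_split(table, 0.77, seed=0)
    sc = fit_scaler(split.train)
    tr, te = apply_scaler(split.train, sc), apply_scaler(split.test, sc)
    net, bank, state, hist = train_primary(tr, quick_config(seed=3))
    bank = collect_test_errors(bank, net, te)
    return tr, te, net, bank, state, hist


class TestTrainPrimary:
    def test_early_stopping_window(self, trained):
        """Training never runs more than best_epoch + patience epochs."""
        *_, hist = trained
        assert hist["stopped_epoch"] - hist["best_epoch"] <= 6

    def test_best_state_has_best_monitored_loss(self, trained):
        tr, te, net, bank, state, hist = trained
        assert hist["best_val_loss"] == min(hist["val_loss"])

    def test_no_weight_update_during_warmup(self, trained):
        *_, state, _ = trained
        assert all(epoch >= 4 for epoch, _ in state.history)

    def test_weight_history_empty_before_delay(self):
        table = make_table([40, 16, 10], seed=2, spread=1.5)
        split = stratified_split(table, 0.77, seed=0)
        tr = apply_scaler(split.train, fit_scaler(split.train))
        cfg = quick_config(primary_epochs=5, patience=3, maal_delay=60)
        _, _, state, _ = train_primary(tr, cfg)
        assert state.history == []
        assert np.array_equal(state.weights, np.ones(3))

    def test_determinism_under_fixed_seed(self):
        table = make_table([40, 16, 10], seed=2, spread=1.5)
        split = stratified_split(table, 0.77, seed=0)
        tr = apply_scaler(split.train, fit_scaler(split.train))
        nets = []
        banks = []
        for _ in range(2):
            net, bank, _, _ = train_primary(tr, quick_config(seed=9))
            nets.append(net)
            banks.append(bank)
        for p, q in zip(nets[0].params(), nets[1].params()):
            assert np.array_equal(p.data, q.data)
        assert banks[0].train_error_ids == banks[1].train_error_ids

    def test_empty_table_rejected(self):
        table = make_table([40, 16, 10], seed=2)
        empty = table.subset_rows(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train_primary(empty, quick_config())


class TestTrainSecondary:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no training data"):
            train_secondary({"inputs": np.empty((0, 64)),
                             "labels": np.array([], dtype=int),
                             "n_classes": 3}, quick_config())

    def test_epoch_cap_respected_and_history_emitted(self, trained, rng):
        tr, te, net, bank, *_ = trained
        split = SplitResult(tr, te, 0.77, 0)
        sec_train, _ = materialize(bank, split, net)
        cfg = quick_config(secondary_epochs=8, patience=5, maal_delay=2)
        sec, state, hist = train_secondary(sec_train, cfg)
        assert hist["stopped_epoch"] <= 8
        assert state.history_array().shape[1] == 1 + 3

    def test_single_class_input_warns_but_trains(self, caplog, rng):
        import logging

        X = rng.standard_normal((12, 64))
        y = np.zeros(12, dtype=int)
        with caplog.at_level(logging.WARNING, logger="macnet.train"):
            sec, *_ = train_secondary(
                {"inputs": X, "labels": y, "n_classes": 3},
                quick_config(secondary_epochs=4, patience=2))
        assert any("single class" in r.message for r in caplog.records)
        assert sec.predict(X).shape == (12,)


class TestJointPrediction:
    def test_oracle_requires_labels(self, trained):
        tr, te, net, *_ = trained
        sec = SecondaryNet(SecondaryNet.default_spec(), seed=0)
        jc = JointClassifier(net, sec, routing="oracle")
        with pytest.raises(ValueError, match="evaluation protocol"):
            joint_predict(jc, te)

    def test_oracle_routing_replaces_only_wrong_predictions(self, trained):
        tr, te, net, bank, *_ = trained
        split = SplitResult(tr, te, 0.77, 0)
        sec_train, _ = materialize(bank, split, net)
        sec, *_ = train_secondary(sec_train, quick_config(seed=5))
        jc = JointClassifier(net, sec, routing="oracle")
        final, audit = joint_predict(jc, te, true_labels=te.labels)
        primary_pred = net.predict(te.features)
        wrong = primary_pred != te.labels
        assert np.array_equal(final[~wrong], primary_pred[~wrong])
        assert len(audit["routed"]) == wrong.sum()
        # structural inequality: correction can only touch wrong predictions
        assert (final == te.labels).mean() >= (primary_pred == te.labels).mean()

    def test_all_correct_primary_routes_nothing(self, trained):
        tr, te, net, *_ = trained
        sec = SecondaryNet(SecondaryNet.default_spec(), seed=0)
        jc = JointClassifier(net, sec, routing="oracle")
        pred = net.predict(te.features)
        final, audit = joint_predict(jc, te, true_labels=pred)
        assert np.array_equal(final, pred)
        assert audit["routed"] == []

    def test_confidence_routing_is_label_free(self, trained):
        tr, te, net, bank, *_ = trained
        split = SplitResult(tr, te, 0.77, 0)
        sec_train, _ = materialize(bank, split, net)
        sec, *_ = train_secondary(sec_train, quick_config(seed=5))
        jc = JointClassifier(net, sec, routing="confidence",
                             confidence_threshold=0.9)
        final, audit = joint_predict(jc, te)
        probs = net.predict_proba(te.features)
        expected_routed = (probs.max(axis=1) < 0.9).sum()
        assert len(audit["routed"]) == expected_routed

    def test_invalid_threshold_rejected(self, trained):
        tr, te, net, *_ = trained
        sec = SecondaryNet(SecondaryNet.default_spec(), seed=0)
        with pytest.raises(ValueError):
            JointClassifier(net, sec, routing="confidence",
                            confidence_threshold=1.5)
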