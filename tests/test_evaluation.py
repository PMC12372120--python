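"""Metrics against independent brute-force oracles."""

import warnings

import numpy as np
import pytest

from macnet.evaluation import (ConfusionMatrix, auc_ovr, bootstrap_ci,
                               cluster_indices, confusion, evaluate, metrics)


# ---------------------------------------------------------------- oracles

def oracle_metrics(y_true, y_pred, C):
    """Direct tallying, no confusion matrix."""
    out = {"accuracy": np.mean(np.asarray(y_true) == np.asarray(y_pred))}
    precision, recall, f1, support = [], [], [], []
    for c in range(C):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precision.append(prec)
        recall.append(rec)
        f1.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        support.append(sum(1 for t in y_true if t == c))
    w = np.array(support) / len(y_true)
    out.update(precision=precision, recall=recall, f1=f1,
               weighted_f1=float(w @ f1))
    return out


def oracle_auc(scores, y_true, c):
    """All positive-negative pairs; ties half credit."""
    pos = [s[c] for s, t in zip(scores, y_true) if t == c]
    neg = [s[c] for s, t in zip(scores, y_true) if t != c]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def oracle_silhouette(X, y):
    n = len(X)
    d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        same = (y == y[i]) & (np.arange(n) != i)
        if not same.any():
            continue
        a = d[i, same].mean()
        b = min(d[i, y == c].mean() for c in np.unique(y) if c != y[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


def oracle_davies_bouldin(X, y):
    classes = np.unique(y)
    cents = np.array([X[y == c].mean(axis=0) for c in classes])
    scatter = np.array([
        np.sqrt(((X[y == c] - cents[k]) ** 2).sum(axis=1)).mean()
        for k, c in enumerate(classes)])
    K = len(classes)
    worst = []
    for i in range(K):
        ratios = [(scatter[i] + scatter[j])
                  / np.sqrt(((cents[i] - cents[j]) ** 2).sum())
                  for j in range(K) if j != i]
        worst.append(max(ratios))
    return float(np.mean(worst))


# ------------------------------------------------------------------ tests

class TestConfusionMetrics:
    def test_binary_example(self):
        m = metrics(ConfusionMatrix([[8, 2], [1, 9]]))
        assert np.isclose(m["accuracy"], 0.85)
        assert np.isclose(m["recall"][1], 0.9)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            C = int(rng.integers(2, 5))
            y_true = rng.integers(0, C, size=200)
            y_pred = rng.integers(0, C, size=200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics(confusion(y_true, y_pred, C))
            o = oracle_metrics(y_true, y_pred, C)
            assert np.isclose(m["accuracy"], o["accuracy"])
            assert np.allclose(m["precision"], o["precision"])
            assert np.allclose(m["recall"], o["recall"])
            assert np.allclose(m["f1"], o["f1"])
            assert np.isclose(m["weighted_f1"], o["weighted_f1"])

    def test_weighted_f1_bounded_by_per_class_extremes(self, rng):
        y_true = rng.integers(0, 3, size=150)
        y_pred = rng.integers(0, 3, size=150)
        m = metrics(confusion(y_true, y_pred, 3))
        assert m["f1"].min() - 1e-12 <= m["weighted_f1"] <= m["f1"].max() + 1e-12

    def test_zero_denominator_convention(self):
        # class 1 never predicted -> precision 0 with warning
        with pytest.warns(UserWarning, match="precision"):
            m = metrics(ConfusionMatrix([[5, 0], [3, 0]]))
        assert m["precision"][1] == 0.0 and m["f1"][1] == 0.0


class TestAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = auc_ovr(scores, [0, 0, 1, 1])
        assert np.allclose(out["per_class"], 1.0)

    def test_constant_scores_give_half(self):
        scores = np.full((10, 2), 0.5)
        out = auc_ovr(scores, [0] * 5 + [1] * 5)
        assert np.allclose(out["per_class"], 0.5)

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(20):
            C = 3
            y = rng.integers(0, C, size=30)
            if len(np.unique(y)) < C:
                continue
            scores = rng.random((30, C)).round(1)  # force some ties
            out = auc_ovr(scores, y)
            for c in range(C):
                assert np.isclose(out["per_class"][c],
                                  oracle_auc(scores, y, c), atol=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=40)
        scores = rng.random((40, 2))
        a = auc_ovr(scores, y)["per_class"]
        b = auc_ovr(np.exp(3 * scores), y)["per_class"]
        assert np.allclose(a, b)

    def test_absent_class_reported_missing(self):
        scores = np.random.default_rng(0).random((10, 3))
        with pytest.warns(UserWarning, match="absent"):
            out = auc_ovr(scores, [0] * 5 + [1] * 5, n_classes=3)
        assert np.isnan(out["per_class"][2])
        assert not np.isnan(out["weighted"])


class TestBootstrap:
    def test_constant_metric_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.zeros(30), np.zeros(30),
                              lambda t, p: 0.42, B=50, seed=0)
        assert lo == hi == 0.42

    def test_percentiles_match_direct_sorting(self):
        """Replay the resampling with the same generator and sort."""
        rng_check = np.random.default_rng(77)
        y = np.random.default_rng(1).integers(0, 2, size=50)
        p = np.random.default_rng(2).integers(0, 2, size=50)

        def acc(t, q):
            return float(np.mean(t == q))

        lo, hi = bootstrap_ci(y, p, acc, B=200, seed=77)
        stats = []
        for _ in range(200):
            idx = rng_check.integers(50, size=50)
            stats.append(acc(y[idx], p[idx]))
        assert np.isclose(lo, np.percentile(stats, 2.5))
        assert np.isclose(hi, np.percentile(stats, 97.5))

    def test_interval_width_shrinks_with_sample_size(self, rng):
        def acc(t, q):
            return float(np.mean(t == q))

        widths = []
        for n in (100, 1000):
            y = rng.integers(0, 2, size=n)
            p = np.where(rng.random(n) < 0.8, y, 1 - y)
            lo, hi = bootstrap_ci(y, p, acc, B=300, seed=5)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_default_resample_count_is_1000(self):
        import inspect

        assert inspect.signature(bootstrap_ci).parameters["B"].default == 1000

    def test_undefined_metric_redrawn(self):
        calls = {"n": 0}

        def flaky(t, p):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise ValueError("undefined")
            return 1.0

        lo, hi = bootstrap_ci(np.arange(10), np.arange(10), flaky, B=20, seed=0)
        assert lo == hi == 1.0


class TestClusterIndices:
    def test_two_tight_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 3)),
                       rng.normal(10, 0.05, (20, 3))])
        y = np.repeat([0, 1], 20)
        sil, db = cluster_indices(X, y)
        assert sil > 0.95 and db < 0.05

    def test_permuted_labels_destroy_structure(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(8, 1, (20, 2))])
        y = rng.integers(0, 2, size=40)  # labels unrelated to the blobs
        sil, _ = cluster_indices(X, y)
        assert sil <= 0.1

    def test_matches_naive_references_exactly(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.integers(0, 3, size=100)
        sil, db = cluster_indices(X, y)
        assert np.isclose(sil, oracle_silhouette(X, y), atol=1e-8)
        assert np.isclose(db, oracle_davies_bouldin(X, y), atol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_indices(rng.standard_normal((10, 2)), np.zeros(10))


class TestEvaluateReport:
    def test_full_report_assembly(self, rng):
        y = rng.integers(0, 3, size=60)
        scores = rng.random((60, 3))
        scores /= scores.sum(1, keepdims=True)
        pred = scores.argmax(1)
        emb = rng.standard_normal((60, 8))
        rep = evaluate(y, pred, 3, scores=scores, embeddings=emb,
                       bootstrap=50, seed=1)
        d = rep.to_dict()
        assert 0 <= d["accuracy"] <= 1
        assert len(d["ci"]["accuracy"]) == 2
        assert d["ci"]["accuracy"][0] <= d["ci"]["accuracy"][1]
        assert np.isfinite(d["silhouette"])
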