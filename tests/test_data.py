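"""Tabular loading, mRMR selection, stratified splitting, standardization."""

import numpy as np
import pytest

from macnet.data import (apply_scaler, fit_scaler, invert_scaler, load_csv,
                         mrmr_select, stratified_split)
from sklearn.metrics import mutual_info_score

from conftest import make_table


class TestLoadCsv:
    def test_row_ids_follow_file_order_and_labels_recode(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("x,y,cls\n1,2,A\n3,4,A\n5,6,B\n7,8,C\n")
        t = load_csv(p, "cls")
        assert t.n_classes == 3
        assert t.row_ids.tolist() == [0, 1, 2, 3]
        assert t.labels.tolist() == [0, 0, 1, 2]
        assert t.label_mapping == {"A": 0, "B": 1, "C": 2}

    def test_nan_cell_fails_loudly_with_coordinates(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("x,y,cls\n1,2,A\n3,,B\n")
        with pytest.raises(ValueError, match=r"row 1.*'y'"):
            load_csv(p, "cls")

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("x,y,cls\n1,2,A\n3,oops,B\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_csv(p, "cls")

    def test_single_class_file_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("x,cls\n1,A\n2,A\n")
        with pytest.raises(ValueError, match="single class"):
            load_csv(p, "cls")


class TestMrmr:
    @staticmethod
    def _fixture():
        # f0 informative, f1 exact copy of f0, f2 label-independent noise
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1, 2], 20)
        f0 = y * 2.0 + rng.normal(0, 0.1, 60)
        f2 = rng.normal(0, 1, 60)
        t = make_table([60], n_features=1)
        from dataclasses import replace

        return replace(
            t,
            features=np.column_stack([f0, f0.copy(), f2]),
            labels=y,
            feature_names=["f0", "f1", "f2"],
            n_classes=3,
        )

    def test_duplicate_feature_never_picked_second(self):
        """Brute-force check: with k=2, greedy must avoid the exact copy.

        Oracle: enumerate all (first, second) candidate orders and score them
        with the same MI/redundancy arithmetic computed independently here.
        """
        table = self._fixture()
        _, selected = mrmr_select(table, k=2, n_bins=5)

        # independent brute-force MID scoring on the same discretization
        import pandas as pd

        disc = [
            np.asarray(pd.qcut(table.features[:, j], 5, labels=False,
                               duplicates="drop"))
            for j in range(3)
        ]
        rel = [mutual_info_score(d, table.labels) for d in disc]
        first = int(np.argmax(rel))
        scores = {
            j: rel[j] - mutual_info_score(disc[j], disc[first])
            for j in range(3) if j != first
        }
        second = min(scores, key=lambda j: (-scores[j], j))
        assert selected[0] == table.feature_names[first]
        assert selected[1] == table.feature_names[second]
        assert {selected[0], selected[1]} != {"f0", "f1"}

    def test_k_equals_p_returns_all_in_greedy_order(self):
        table = self._fixture()
        sub, selected = mrmr_select(table, k=3, n_bins=5)
        assert sorted(selected) == ["f0", "f1", "f2"]
        assert sub.n_features == 3

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            mrmr_select(self._fixture(), k=4)

    def test_selection_is_deterministic(self):
        table = self._fixture()
        a = mrmr_select(table, k=2)[1]
        b = mrmr_select(table, k=2)[1]
        assert a == b

    def test_requested_width_honored(self, small_table):
        sub, sel = mrmr_select(small_table, k=2)
        assert sub.n_features == 2 and len(sel) == 2


class TestStratifiedSplit:
    def test_largest_remainder_allocation(self):
        """Hand-checked: [100, 20, 10] at 0.77 -> train [77, 15, 8]."""
        table = make_table([100, 20, 10], seed=1)
        res = stratified_split(table, 0.77, seed=5)
        assert res.train.class_counts().tolist() == [77, 15, 8]
        assert res.test.class_counts().tolist() == [23, 5, 2]

    def test_deterministic_partition(self, small_table):
        a = stratified_split(small_table, 0.77, seed=42)
        b = stratified_split(small_table, 0.77, seed=42)
        assert set(a.train.row_ids) == set(b.train.row_ids)

    def test_disjoint_and_stratified_over_many_seeds(self):
        for seed in range(25):
            table = make_table([40, 17, 9], seed=seed)
            frac = 0.5 + (seed % 5) / 10.0
            res = stratified_split(table, frac, seed=seed)
            assert not set(res.train.row_ids) & set(res.test.row_ids)
            expected = table.class_counts() * frac
            got = res.train.class_counts()
            assert (np.abs(got - expected) <= 1).all()

    def test_singleton_class_rejected(self):
        table = make_table([10, 1], seed=0)
        with pytest.raises(ValueError, match="class 1"):
            stratified_split(table, 0.77, seed=0)


class TestScaler:
    def test_population_zscore_values(self):
        """mu=2, sigma=sqrt(2/3): [1,2,3] -> [-1.2247, 0, 1.2247]."""
        t = make_table([3], n_features=1)
        from dataclasses import replace

        t = replace(t, features=np.array([[1.0], [2.0], [3.0]]))
        params = fit_scaler(t)
        z = apply_scaler(t, params).features.ravel()
        assert np.allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_train_columns_become_standard(self, small_table):
        params = fit_scaler(small_table)
        z = apply_scaler(small_table, params)
        assert np.abs(z.features.mean(axis=0)).max() < 1e-9
        assert np.allclose(z.features.std(axis=0, ddof=0), 1.0)

    def test_idempotent_on_zscores(self, small_table):
        params = fit_scaler(small_table)
        z = apply_scaler(small_table, params)
        z2 = apply_scaler(z, fit_scaler(z))
        assert np.allclose(z.features, z2.features, atol=1e-9)

    def test_round_trip(self, small_table):
        params = fit_scaler(small_table)
        back = invert_scaler(apply_scaler(small_table, params), params)
        assert np.allclose(back.features, small_table.features, atol=1e-9)

    def test_constant_feature_rejected(self):
        t = make_table([5], n_features=2)
        t.features[:, 1] = 3.14
        with pytest.raises(ValueError, match="f1"):
            fit_scaler(t)
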