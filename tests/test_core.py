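import numpy as np
import pandas as pd
import pytest

from spiderfs.core import (
    ClassCountError,
    EmptyTableError,
    MissingLabelColumnError,
    MissingValueError,
    NonNumericCellError,
    SplitSpec,
    imbalance_ratio,
    load_expression_table,
    make_cv_folds,
    split_train_test,
    write_expression_table,
)
from spiderfs.synthetic import SyntheticSpec, generate_synthetic_dataset


def _write_table(path, rows, header="sample,f1,f2,class"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestLoader:
    def test_shape_and_label_encoding(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_table(p, ["s1,1,2,A", "s2,3,4,A", "s3,5,6,B", "s4,7,8,B"])
        ds = load_expression_table(p)
        assert ds.n_samples == 4 and ds.n_features == 2
        assert set(ds.labels) == {1, -1}
        assert ds.feature_names == ("f1", "f2")

    def test_minority_maps_to_plus_one(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_table(p, ["s1,1,2,A", "s2,3,4,B", "s3,5,6,B", "s4,7,8,B"])
        ds = load_expression_table(p)
        assert ds.label_names[1] == "A"
        assert int(np.sum(ds.labels == 1)) == 1

    def test_features_in_rows_orientation(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("gene,s1,s2,s3,s4\nf1,1,3,5,7\nf2,2,4,6,8\nclass,0,0,1,1\n")
        ds = load_expression_table(p, orientation="features-in-rows")
        assert ds.n_samples == 4 and ds.n_features == 2
        np.testing.assert_allclose(ds.matrix[:, 0], [1, 3, 5, 7])

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_table(p, ["s1,1,2,A", "s2,oops,4,A", "s3,5,6,B", "s4,7,8,B"])
        with pytest.raises(NonNumericCellError, match="oops.*s2.*f1"):
            load_expression_table(p)

    @pytest.mark.parametrize(
        "rows,err",
        [
            (["s1,1,2,A", "s2,3,4,A"], ClassCountError),  # one class
            (["s1,1,2,A", "s2,3,4,B", "s3,5,6,C"], ClassCountError),  # three
        ],
    )
    def test_class_count_validation(self, tmp_path, rows, err):
        p = tmp_path / "t.csv"
        _write_table(p, rows)
        with pytest.raises(err):
            load_expression_table(p)

    def test_missing_label_column(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_table(p, ["s1,1,2,A", "s2,3,4,B"], header="sample,f1,f2,label")
        with pytest.raises(MissingLabelColumnError):
            load_expression_table(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("")
        with pytest.raises(EmptyTableError):
            load_expression_table(p)

    def test_missing_values_rejected_then_imputed(self, tmp_path):
        p = tmp_path / "t.csv"
        _write_table(p, ["s1,1,,A", "s2,3,4,A", "s3,5,6,B", "s4,7,8,B"])
        with pytest.raises(MissingValueError):
            load_expression_table(p)
        ds = load_expression_table(p, impute_missing=True)
        assert ds.matrix[0, 1] == pytest.approx(6.0)  # mean of 4, 6, 8

    def test_round_trip(self, tmp_path):
        ds, _ = generate_synthetic_dataset(SyntheticSpec(n_samples=20, n_noise=10, seed=3))
        p = tmp_path / "rt.csv"
        write_expression_table(ds, p)
        back = load_expression_table(p)
        np.testing.assert_allclose(back.matrix, ds.matrix)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert back.feature_names == ds.feature_names


class TestSplitting:
    def _balanced(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        from spiderfs.core import ExpressionDataset

        return ExpressionDataset(
            matrix=rng.standard_normal((n, 3)),
            labels=np.array([1] * (n // 2) + [-1] * (n // 2)),
            feature_names=("a", "b", "c"),
            sample_ids=tuple(f"s{i}" for i in range(n)),
        )

    def test_balanced_80_20(self):
        ds = self._balanced()
        tr, te = split_train_test(ds, SplitSpec(seed=1))
        assert tr.n_samples == 80 and te.n_samples == 20
        assert int(np.sum(tr.labels == 1)) == 40
        assert int(np.sum(te.labels == 1)) == 10

    def test_deterministic_and_partition(self):
        ds = self._balanced()
        tr1, te1 = split_train_test(ds, SplitSpec(seed=5))
        tr2, te2 = split_train_test(ds, SplitSpec(seed=5))
        assert tr1.sample_ids == tr2.sample_ids and te1.sample_ids == te2.sample_ids
        assert set(tr1.sample_ids) | set(te1.sample_ids) == set(ds.sample_ids)
        assert set(tr1.sample_ids).isdisjoint(te1.sample_ids)

    def test_table1_shaped_40_22_split(self):
        """Stratified counts for a 40/22 two-class dataset at 0.8."""
        from spiderfs.core import ExpressionDataset

        rng = np.random.default_rng(0)
        ds = ExpressionDataset(
            matrix=rng.standard_normal((62, 2)),
            labels=np.array([-1] * 40 + [1] * 22),
            feature_names=("a", "b"),
            sample_ids=tuple(f"s{i}" for i in range(62)),
        )
        tr, _ = split_train_test(ds, SplitSpec(seed=2))
        n_maj = int(np.sum(tr.labels == -1))
        n_min = int(np.sum(tr.labels == 1))
        # proportional expectation 32 / 17.6, within one sample
        assert n_maj in (31, 32, 33)
        assert n_min in (17, 18)
        assert n_maj + n_min in (49, 50)

    def test_too_small_class_raises(self):
        from spiderfs.core import ExpressionDataset

        ds = ExpressionDataset(
            matrix=np.zeros((5, 2)),
            labels=np.array([1, -1, -1, -1, -1]),
            feature_names=("a", "b"),
            sample_ids=tuple("abcde"),
        )
        with pytest.raises(ClassCountError):
            split_train_test(ds, SplitSpec())


class TestFolds:
    def test_partition_property(self):
        ds, _ = generate_synthetic_dataset(SyntheticSpec(n_samples=50, n_noise=5, seed=2))
        folds = make_cv_folds(ds, SplitSpec(n_folds=5, seed=0))
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val.tolist()) == list(range(ds.n_samples))
        for tr, va in folds:
            assert set(tr).isdisjoint(va)
            assert sorted(set(tr) | set(va)) == list(range(ds.n_samples))

    def test_stratification_6_4_two_folds(self):
        from spiderfs.core import ExpressionDataset

        ds = ExpressionDataset(
            matrix=np.arange(20, dtype=float).reshape(10, 2),
            labels=np.array([-1] * 6 + [1] * 4),
            feature_names=("a", "b"),
            sample_ids=tuple(f"s{i}" for i in range(10)),
        )
        folds = make_cv_folds(ds, SplitSpec(n_folds=2, seed=0))
        for _, va in folds:
            assert int(np.sum(ds.labels[va] == -1)) == 3
            assert int(np.sum(ds.labels[va] == 1)) == 2

    def test_determinism(self):
        ds, _ = generate_synthetic_dataset(SyntheticSpec(n_samples=40, n_noise=5, seed=4))
        f1 = make_cv_folds(ds, SplitSpec(seed=9))
        f2 = make_cv_folds(ds, SplitSpec(seed=9))
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_folds_exceeding_minority_raise(self, tiny_dataset):
        with pytest.raises(ClassCountError):
            make_cv_folds(tiny_dataset, SplitSpec(n_folds=3, seed=0))


class TestImbalanceRatio:
    @pytest.mark.parametrize(
        "n_a,n_b,expected",
        [(47, 25, 1.88), (50, 50, 1.00), (162, 91, 1.78), (40, 22, 1.82), (40, 18, 2.22)],
    )
    def test_printed_count_ratios(self, n_a, n_b, expected):
        labels = np.array([1] * n_b + [-1] * n_a)
        assert imbalance_ratio(labels) == expected

    def test_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1 = int(rng.integers(1, 50))
            n2 = int(rng.integers(1, 50))
            r = imbalance_ratio(np.array([1] * n1 + [-1] * n2))
            assert r >= 1.0
            assert (r == 1.0) == (n1 == n2)

    def test_single_class_raises(self):
        with pytest.raises(ClassCountError):
            imbalance_ratio(np.array([1, 1, 1]))
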